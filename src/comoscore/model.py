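"""Model/Results facade over the full comorbidity-comparison analysis.

:class:`ComorbidityMortality` is built from an episode cohort (or a wide
DataFrame / CSV); its :meth:`~ComorbidityMortality.fit` runs the whole
pipeline — adult/non-obstetric filter, ICD-10 category flagging under both
schemes, CCI/ECI/WCI scoring, quartile strata, pairwise agreement
(Spearman's rho, ICC absolute agreement), age-adjusted logistic models,
ROC/AUC with DeLong comparisons — and returns a
:class:`ComorbidityMortalityResults` carrying every output table plus a
``summary()`` in the spirit of statsmodels results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import io as mio
from . import mapping, mortality, scoring
from .exceptions import ValidationError

INDEX_LABELS = {"cci": "Charlson", "eci": "Elixhauser", "wci": "van Walraven"}


class ComorbidityMortality:
    """Comparison of CCI/ECI/WCI as predictors of in-hospital death.

    Parameters
    ----------
    cohort
        An :class:`comoscore.io.Cohort` of hospitalization episodes.
    min_age
        Adult filter threshold; episodes younger than this or flagged
        obstetric are excluded before analysis. ``None`` disables filtering.
    include_main_dx
        Whether the main diagnosis counts toward comorbidity (default) or
        only secondary diagnoses do.
    cutpoints
        Optional dict index-name -> (c1, c2, c3) explicit strata cutpoints;
        empirical quartiles are used where omitted.
    age_cut
        Age dichotomization point for the logistic models; defaults to the
        filtered cohort's median age.
    predictor_mode
        ROC predictor: ``"model_probability"`` (fitted ordinal-model
        probability, default) or ``"raw_score"``.
    """

    def __init__(
        self,
        cohort: mio.Cohort,
        min_age: int | None = 19,
        include_main_dx: bool = True,
        cutpoints: dict[str, tuple[float, float, float]] | None = None,
        age_cut: float | None = None,
        predictor_mode: str = "model_probability",
        quantile_convention: str = "stata",
    ):
        self.raw_cohort = cohort
        self.min_age = min_age
        self.include_main_dx = include_main_dx
        self.cutpoints = cutpoints or {}
        self.age_cut = age_cut
        self.predictor_mode = predictor_mode
        self.quantile_convention = quantile_convention
        self.charlson_map = mapping.load_map(mapping.CHARLSON)
        self.elixhauser_map = mapping.load_map(mapping.ELIXHAUSER)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ComorbidityMortality":
        """Build from a wide-layout episode DataFrame."""
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            df.to_csv(fh, index=False)
            path = fh.name
        cohort = mio.read_episodes(path, layout="wide")
        Path(path).unlink()
        return cls(cohort, **kwargs)

    @classmethod
    def from_csv(cls, path, layout: str = "wide", **kwargs) -> "ComorbidityMortality":
        return cls(mio.read_episodes(path, layout=layout), **kwargs)

    def fit(self) -> "ComorbidityMortalityResults":
        cohort = self.raw_cohort
        n_input = len(cohort)
        if self.min_age is not None:
            cohort = mio.filter_cohort(cohort, min_age=self.min_age)
        n_analyzed = len(cohort)

        cha_flags = mapping.flag_cohort(cohort, self.charlson_map, self.include_main_dx)
        elix_flags = mapping.flag_cohort(cohort, self.elixhauser_map, self.include_main_dx)
        scores = scoring.scores_from_frames(
            cha_flags, elix_flags, self.charlson_map, self.elixhauser_map
        )

        strata: dict[str, scoring.StrataAssignment] = {}
        for name in scoring.INDEX_NAMES:
            strata[name] = scoring.assign_strata(
                scores[name].to_numpy(),
                index_name=name,
                cutpoints=self.cutpoints.get(name),
                convention=self.quantile_convention,
            )

        agreement_table = agr.agreement_table(
            {name: strata[name].strata for name in scoring.INDEX_NAMES}
        )
        age_cut = self.age_cut if self.age_cut is not None else cohort.median_age
        comparison = mortality.compare_indices(
            cohort, strata, predictor_mode=self.predictor_mode,
            age_cut=age_cut, scores=scores,
        )
        summary_table = scoring.summarize_cohort(
            cohort, scores, convention=self.quantile_convention
        )
        freq_cha = mapping.frequencies_from_frame(cha_flags)
        freq_elix = mapping.frequencies_from_frame(elix_flags)

        manifest = {
            "n_input": n_input,
            "n_rejected_rows": len(self.raw_cohort.rejections),
            "n_excluded_filter": n_input - n_analyzed,
            "n_analyzed": n_analyzed,
            "min_age": self.min_age,
            "include_main_dx": self.include_main_dx,
            "age_cut": float(age_cut),
            "predictor_mode": self.predictor_mode,
            "quantile_convention": self.quantile_convention,
            "cutpoints": {k: list(map(float, v.cutpoints)) for k, v in strata.items()},
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

        return ComorbidityMortalityResults(
            model=self,
            cohort=cohort,
            charlson_flags=cha_flags,
            elixhauser_flags=elix_flags,
            scores=scores,
            strata=strata,
            agreement=agreement_table,
            comparison=comparison,
            cohort_summary=summary_table,
            charlson_frequencies=freq_cha,
            elixhauser_frequencies=freq_elix,
            manifest=manifest,
        )


@dataclass
class ComorbidityMortalityResults:
    """Fitted pipeline outputs with summary, export and plotting helpers."""

    model: ComorbidityMortality
    cohort: mio.Cohort
    charlson_flags: pd.DataFrame
    elixhauser_flags: pd.DataFrame
    scores: pd.DataFrame
    strata: dict[str, scoring.StrataAssignment]
    agreement: pd.DataFrame
    comparison: mortality.IndexComparison
    cohort_summary: pd.DataFrame
    charlson_frequencies: pd.DataFrame
    elixhauser_frequencies: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def auc_table(self) -> pd.DataFrame:
        return mortality.auc_table(self.comparison.rocs)

    @property
    def delong_table(self) -> pd.DataFrame:
        return mortality.delong_table(self.comparison.delong)

    @property
    def or_table(self) -> pd.DataFrame:
        """Stacked OR table: per index the ordinal 'all strata' row, the
        per-stratum rows against stratum 1, and the age row."""
        parts = []
        for name in self.strata:
            ord_tab = self.comparison.fits_ordinal[name].or_table.copy()
            cat_tab = self.comparison.fits_categorical[name].or_table.copy()
            block = pd.concat(
                [ord_tab.iloc[[0]], cat_tab], ignore_index=True
            )
            block.insert(0, "index", name)
            parts.append(block)
        return pd.concat(parts, ignore_index=True)

    @property
    def strata_table(self) -> pd.DataFrame:
        parts = []
        for name, sa in self.strata.items():
            t = sa.interval_table.copy()
            t.insert(0, "index", name)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)

    def scores_table(self) -> pd.DataFrame:
        out = self.scores.copy()
        for name, sa in self.strata.items():
            out[f"stratum_{name}"] = sa.strata
        return out.reset_index()

    def summary(self) -> str:
        """Human-readable account of the whole comparison."""
        lines = []
        n = len(self.cohort)
        lines.append("Comorbidity indices vs in-hospital mortality")
        lines.append("=" * 60)
        lines.append(
            f"Episodes analyzed: {n}   deaths: "
            f"{sum(e.death for e in self.cohort.episodes)} "
            f"({100 * self.cohort.mortality_rate:.2f}%)   "
            f"median age: {self.cohort.median_age:.0f}"
        )
        lines.append("")
        lines.append("Score medians (IQR):")
        for _, row in self.cohort_summary.iterrows():
            if str(row["variable"]).endswith("_median") and row["variable"] not in (
                "age_median", "length_of_stay_median"
            ):
                name = row["variable"].replace("_median", "")
                lines.append(
                    f"  {name.upper():4s} {row['value']:g} "
                    f"({row['iqr_low']:g}-{row['iqr_high']:g})"
                )
        lines.append("")
        lines.append("Agreement between strata (Spearman rho / ICC absolute):")
        for _, r in self.agreement.iterrows():
            lines.append(
                f"  {r['index_a']} vs {r['index_b']}: rho={r['rho']:.3f} "
                f"({r['label_rho']}), ICC_A={r['icc_a']:.3f} "
                f"[{r['icc_ci_low']:.3f}, {r['icc_ci_high']:.3f}] ({r['label_icc']})"
            )
        lines.append("")
        lines.append("Discrimination (AUC, DeLong 95% CI):")
        for _, r in self.auc_table.iterrows():
            lines.append(
                f"  {r['index']}: AUC={r['auc']:.3f} "
                f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}]"
            )
        lines.append(f"  ranking: {' > '.join(self.comparison.ranking)}")
        lines.append("")
        lines.append("Paired AUC differences (DeLong):")
        for _, r in self.delong_table.iterrows():
            lines.append(
                f"  {r['index_a']} - {r['index_b']}: diff={r['auc_diff']:+.4f} "
                f"z={r['z']:.2f} p={r['p']:.3g}"
            )
        lines.append("")
        lines.append("Adjusted odds ratios (vs stratum 1; 'all strata' per unit stratum):")
        for _, r in self.or_table.iterrows():
            ci = (
                ""
                if np.isnan(r["ci_low"])
                else f" [{r['ci_low']:.2f}, {r['ci_high']:.2f}]"
            )
            lines.append(f"  {r['covariate']}: OR={r['or']:.2f}{ci}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curves for the three indices on one axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for name, roc in self.comparison.rocs.items():
            ax.plot(
                roc.points[:, 0], roc.points[:, 1],
                label=f"{INDEX_LABELS.get(name, name)} (AUC={roc.auc:.3f})",
            )
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("Sensitivity")
        ax.legend(loc="lower right")
        return ax

    def save_tables(self, outdir) -> dict:
        """Write every output table (and the manifest) under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "summary.csv": self.cohort_summary,
            "charlson_frequencies.csv": self.charlson_frequencies,
            "elixhauser_frequencies.csv": self.elixhauser_frequencies,
            "scores.csv": self.scores_table(),
            "strata_table.csv": self.strata_table,
            "agreement.csv": self.agreement,
            "or_table.csv": self.or_table,
            "auc_table.csv": self.auc_table,
            "delong_table.csv": self.delong_table,
        }
        for name, tab in tables.items():
            mio.write_table(tab, outdir / name)
        roc_rows = []
        for name, roc in self.comparison.rocs.items():
            for fpr, tpr in roc.points:
                roc_rows.append({"index": name, "fpr": fpr, "tpr": tpr})
        mio.write_table(pd.DataFrame(roc_rows), outdir / "roc_points.csv")
        mio.write_manifest(self.manifest, outdir / "manifest.json")
        return {**{k: str(outdir / k) for k in tables}, "manifest": str(outdir / "manifest.json")}
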