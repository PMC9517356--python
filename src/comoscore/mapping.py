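"""ICD-10 comorbidity coding algorithms: Charlson (17 categories) and
Elixhauser (31 categories, van Walraven weights).

A :class:`ComorbidityMap` is a validated, ordered list of
:class:`CategoryDef` plus severity hierarchy pairs. Matching is by code
*family*: a normalized diagnosis code belongs to a category when any of the
category's prefixes is a leading substring of the code (so prefix ``I50``
captures ``I500``–``I509``). Hierarchies then demote the milder member of a
(superior, inferior) pair — e.g. metastatic cancer suppresses "solid tumor
without metastasis" — so one condition is never double counted.

Maps ship as editable CSV files under :mod:`comoscore.data`; they are loaded
and structurally validated by :func:`load_map`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import MalformedCodeError, MapIntegrityError, ValidationError

CHARLSON = "charlson"
ELIXHAUSER = "elixhauser"

_CODE_RE = re.compile(r"^[A-Z][0-9]")
_PREFIX_RE = re.compile(r"^[A-Z0-9]{3,}$")


def normalize_code(raw: str) -> str:
    """Normalize a raw ICD-10 code: uppercase, strip whitespace and dots.

    Raises :class:`MalformedCodeError` if the result is empty, does not start
    with a letter A-Z, or has a non-digit second character.
    """
    if raw is None:
        raise MalformedCodeError("empty diagnosis code")
    code = re.sub(r"[\s.]", "", str(raw)).upper()
    if not code:
        raise MalformedCodeError("empty diagnosis code")
    if not _CODE_RE.match(code):
        raise MalformedCodeError(f"malformed ICD-10 code: {raw!r}")
    return code


@dataclass(frozen=True)
class CategoryDef:
    """One comorbidity category: label, scheme, code prefixes and weights."""

    label: str
    scheme: str
    icd10_prefixes: tuple[str, ...]
    charlson_weight: int | None = None
    vw_weight: int | None = None

    def __post_init__(self) -> None:
        if not self.icd10_prefixes:
            raise MapIntegrityError(f"{self.label}: empty prefix list")
        for p in self.icd10_prefixes:
            if not _PREFIX_RE.match(p):
                raise MapIntegrityError(
                    f"{self.label}: invalid prefix {p!r} (need uppercase "
                    "alphanumeric, no dots, length >= 3)"
                )
        if self.scheme == CHARLSON and self.charlson_weight is None:
            raise MapIntegrityError(f"{self.label}: missing Charlson weight")
        if self.scheme == ELIXHAUSER and self.vw_weight is None:
            raise MapIntegrityError(f"{self.label}: missing van Walraven weight")


@dataclass
class ComorbidityMap:
    """An ordered comorbidity coding algorithm for one scheme."""

    scheme: str
    categories: list[CategoryDef]
    hierarchy_rules: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise MapIntegrityError(f"{self.scheme}: duplicate category labels")
        expected = {CHARLSON: 17, ELIXHAUSER: 31}.get(self.scheme)
        if expected is not None and len(self.categories) != expected:
            raise MapIntegrityError(
                f"{self.scheme} map must have {expected} categories, "
                f"got {len(self.categories)}"
            )
        for sup, inf in self.hierarchy_rules:
            if sup not in labels or inf not in labels:
                raise MapIntegrityError(
                    f"hierarchy pair ({sup!r}, {inf!r}) references unknown label"
                )
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.categories]

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def index_of(self, label: str) -> int:
        return self._index[label]

    def weights(self, kind: str) -> np.ndarray:
        """Integer weight vector aligned with category order.

        ``kind`` is ``"charlson"`` or ``"vw"``.
        """
        if kind == "charlson":
            return np.array([c.charlson_weight for c in self.categories], dtype=int)
        if kind == "vw":
            return np.array([c.vw_weight for c in self.categories], dtype=int)
        raise ValidationError(f"unknown weight kind {kind!r}")

    def hierarchy_index_pairs(self) -> list[tuple[int, int]]:
        return [(self._index[s], self._index[i]) for s, i in self.hierarchy_rules]


@dataclass(frozen=True)
class ComorbidityProfile:
    """Post-hierarchy boolean category flags for one episode."""

    episode_id: str
    scheme: str
    flags: tuple[bool, ...]


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("comoscore.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#", dtype=str)


def load_map(scheme: str, apply_hierarchy_rules: bool = True) -> ComorbidityMap:
    """Load and validate the packaged map for ``scheme``.

    ``apply_hierarchy_rules=False`` loads the map with severity exclusions
    switched off (every matched category then counts).
    """
    if scheme not in (CHARLSON, ELIXHAUSER):
        raise ValidationError(f"unknown scheme {scheme!r}")
    fname = f"{scheme}_map.csv"
    df = _read_packaged_csv(fname)
    cats: list[CategoryDef] = []
    for _, row in df.iterrows():
        if row["scheme"] != scheme:
            raise MapIntegrityError(f"{fname}: row scheme {row['scheme']!r}")
        cw = row.get("charlson_weight")
        vw = row.get("vw_weight")
        cats.append(
            CategoryDef(
                label=row["label"],
                scheme=scheme,
                icd10_prefixes=tuple(row["prefixes"].split(";")),
                charlson_weight=None if pd.isna(cw) else int(cw),
                vw_weight=None if pd.isna(vw) else int(vw),
            )
        )
    rules: list[tuple[str, str]] = []
    if apply_hierarchy_rules:
        hdf = _read_packaged_csv("hierarchy.csv")
        rules = [
            (r["superior"], r["inferior"])
            for _, r in hdf.iterrows()
            if r["scheme"] == scheme
        ]
    return ComorbidityMap(scheme=scheme, categories=cats, hierarchy_rules=rules)


def code_categories(code: str, cmap: ComorbidityMap) -> list[int]:
    """Indices of every category whose prefix family contains ``code``.

    ``code`` must already be normalized.
    """
    out = []
    for i, cat in enumerate(cmap.categories):
        if any(code.startswith(p) for p in cat.icd10_prefixes):
            out.append(i)
    return out


def apply_hierarchy(flags: Sequence[bool] | np.ndarray, cmap: ComorbidityMap) -> np.ndarray:
    """Demote inferior categories wherever a (superior, inferior) pair co-occurs.

    Idempotent; returns a new boolean array aligned with the map.
    """
    out = np.asarray(flags, dtype=bool).copy()
    if out.shape[-1] != cmap.n_categories:
        raise ValidationError("flag vector not aligned with map")
    for sup, inf in cmap.hierarchy_index_pairs():
        out[..., inf] &= ~out[..., sup]
    return out


def flag_comorbidities(
    episode,
    cmap: ComorbidityMap,
    include_main_dx: bool = True,
) -> ComorbidityProfile:
    """Map one episode's diagnoses to post-hierarchy category flags.

    With ``include_main_dx=False`` only secondary diagnoses (positions 2+)
    are considered, the classical reading of comorbidity.
    """
    codes = list(episode.diagnoses)
    if not include_main_dx:
        codes = codes[1:]
    flags = np.zeros(cmap.n_categories, dtype=bool)
    for pos, raw in enumerate(codes, start=1 if include_main_dx else 2):
        try:
            code = normalize_code(raw)
        except MalformedCodeError as exc:
            raise MalformedCodeError(
                f"episode {episode.episode_id}, diagnosis position {pos}: {exc}"
            ) from exc
        for i in code_categories(code, cmap):
            flags[i] = True
    flags = apply_hierarchy(flags, cmap)
    return ComorbidityProfile(
        episode_id=episode.episode_id, scheme=cmap.scheme, flags=tuple(bool(f) for f in flags)
    )


def flag_cohort(
    cohort,
    cmap: ComorbidityMap,
    include_main_dx: bool = True,
) -> pd.DataFrame:
    """Vectorized cohort-level flagging.

    Returns a boolean DataFrame indexed by episode_id with one column per
    category (map order), after hierarchy. Equivalent to calling
    :func:`flag_comorbidities` per episode but caches the prefix lookup per
    distinct code, which matters for registry-sized cohorts.
    """
    ids = []
    code_lists = []
    for ep in cohort.episodes:
        codes = ep.diagnoses if include_main_dx else ep.diagnoses[1:]
        ids.append(ep.episode_id)
        code_lists.append([normalize_code(c) for c in codes])

    lookup: dict[str, list[int]] = {}
    n_cat = cmap.n_categories
    flags = np.zeros((len(ids), n_cat), dtype=bool)
    for row, codes in enumerate(code_lists):
        for code in codes:
            hit = lookup.get(code)
            if hit is None:
                hit = code_categories(code, cmap)
                lookup[code] = hit
            for i in hit:
                flags[row, i] = True
    flags = apply_hierarchy(flags, cmap)
    return pd.DataFrame(flags, index=pd.Index(ids, name="episode_id"), columns=cmap.labels)


def profiles_from_frame(frame: pd.DataFrame, cmap: ComorbidityMap) -> list[ComorbidityProfile]:
    """Convert a boolean flag frame (as from :func:`flag_cohort`) to profiles."""
    return [
        ComorbidityProfile(episode_id=str(idx), scheme=cmap.scheme, flags=tuple(map(bool, row)))
        for idx, row in zip(frame.index, frame.to_numpy())
    ]


def category_frequencies(profiles: Iterable[ComorbidityProfile]) -> pd.DataFrame:
    """Per-category prevalence: percent of profiles with the flag set.

    All profiles must share one scheme; output rows follow map order
    (i.e. the order of the flags vector).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles")
    schemes = {p.scheme for p in profiles}
    if len(schemes) > 1:
        raise ValidationError(f"mixed schemes {schemes}")
    scheme = profiles[0].scheme
    cmap = load_map(scheme)
    mat = np.array([p.flags for p in profiles], dtype=bool)
    if mat.shape[1] != cmap.n_categories:
        raise ValidationError("profile flags not aligned with packaged map")
    pct = 100.0 * mat.mean(axis=0)
    return pd.DataFrame({"label": cmap.labels, "percent": pct})


def frequencies_from_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Prevalence table straight from a boolean flag frame."""
    pct = 100.0 * frame.to_numpy(dtype=bool).mean(axis=0)
    return pd.DataFrame({"label": list(frame.columns), "percent": pct})
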