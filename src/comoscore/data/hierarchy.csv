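# Severity hierarchies of the Quan coding-algorithm lineage: when both members
# of a pair are flagged for one episode, the milder (inferior) category is
# switched off so a condition is counted once at its most severe level.
scheme,superior,inferior
charlson,Diabetes with chronic complication,Diabetes without chronic complication
charlson,Moderate or severe liver disease,Mild liver disease
charlson,Metastatic solid tumor,"Any malignancy, including lymphoma and leukemia, except malignant neoplasm of skin"
elixhauser,"Diabetes, complicated","Diabetes, uncomplicated"
elixhauser,Metastatic cancer,Solid tumor without metastasis
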