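# Synthetic layout template for a spike-in reference table.
# Columns: spikein_id<TAB>molecules
# `molecules` is the expected number of spike-in molecules per
# cell-equivalent sample BEFORE any dilution factor; pass --dilution to
# scale. The ids below follow the External RNA Controls Consortium naming
# convention but the concentrations are synthetic placeholders — replace
# both with the values for the spike-in mix actually used.
spikein_id	molecules
ERCC-00002	15000
ERCC-00003	937.5
ERCC-00004	7500
ERCC-00009	234.375
ERCC-00012	0.9155
ERCC-00013	29.296875
ERCC-00014	3.6621
ERCC-00016	0.2289
ERCC-00017	0.0572
ERCC-00019	58.59375
ERCC-00022	468.75
ERCC-00024	0.4578
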