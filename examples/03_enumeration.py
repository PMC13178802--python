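"""Four routes to microbial abundance per gram of soil.

Runs the plate-count, most-probable-number, DNA-yield and epifluorescence
estimators on small raw observations and prints the comparison table.
"""

from ecostoich.quantification import (
    DNAYieldObservation, MicroscopyMosaic, MPNObservation, PlateObservation,
    cfu_per_gram, epi_cells_per_gram, method_comparison_table, mpn_estimate,
    tde_cells_per_gram,
)

plate = cfu_per_gram(PlateObservation(
    sample_id="s1", compartment="soil", organism="bacteria", colony_count=95,
    dilution_factor=1e3, plated_volume=0.1, suspension_volume=10.0, sample_mass=1.0))

mpn = mpn_estimate(MPNObservation(
    sample_id="s1", dilution_levels=((1e-6, 5, 5), (1e-7, 5, 3), (1e-8, 5, 0))))
print(f"MPN = {mpn.value:.3g} /g, 95% CI [{mpn.ci_lower:.3g}, {mpn.ci_upper:.3g}]")

tde = tde_cells_per_gram(DNAYieldObservation("s1", dna_mass=2035.0, sample_mass=0.25))

viable, total, viability = epi_cells_per_gram(MicroscopyMosaic(
    sample_id="s1", field_counts_live=(80,) * 25, field_counts_dead=(20,) * 25,
    field_area=1e4, filter_area=1e8, suspension_volume=10.0,
    aliquot_volume=0.01, sample_mass=1.0))
print(f"EPI viability fraction = {viability:.2f}")

print(method_comparison_table([plate, mpn, tde, viable, total]).round(2).to_string(index=False))

# The culture-dependent counts (CFU, MPN) sit around 1e7/g while the
# culture-independent ones (TDE, EPI) sit near 1e9/g: the two-log gap is
# the classic "great plate count anomaly" between culturable and total
# communities.
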