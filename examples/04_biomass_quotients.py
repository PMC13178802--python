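"""Microbial biomass, respiration and the physiological quotients.

From raw fumigation-extraction and alkali-trap readings to qCO2 (stress)
and Cmic/Corg (carbon availability).
"""

from ecostoich.microbial_params import (
    BiomassAssayRecord, RespirationRecord, basal_respiration, mbc, mbn,
    metabolic_quotient, microbial_quotient,
)

bio = BiomassAssayRecord(
    sample_id="s1", group="A. sisalana",
    C_fumigated=351.7, C_unfumigated=150.0,
    N_fumigated=24.54, N_unfumigated=20.0,
)
resp = RespirationRecord(
    sample_id="s1", group="A. sisalana",
    blank_titre=10.0, sample_titre=9.722, acid_molarity=0.1,
    soil_mass=10.0, incubation_time=24.0,
)

MBC, _ = mbc(bio)
MBN, _ = mbn(bio)
MR, _ = basal_respiration(resp)
print(f"MBC = {MBC:.2f} umol C/g, MBN = {MBN:.2f} umol N/g")
print(f"basal respiration = {MR:.2f} umol CO2/g/day")
print(f"qCO2 = {metabolic_quotient(MR, MBC):.2f} mg CO2/g MBC/h")
print(f"Cmic/Corg = {microbial_quotient(MBC, TOC=21.75):.2f} %")

# A low metabolic quotient with ~2 % of organic carbon held in living
# biomass indicates a growth-oriented, unstressed community; stressed
# communities burn more carbon per unit biomass and hold less of the
# soil's carbon.
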