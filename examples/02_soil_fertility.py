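"""Fertility indices from a routine soil chemistry panel.

Derives organic carbon, molar nutrient ratios and the cation-based
fertility indices, then prints the qualitative classification.
"""

from ecostoich.soil_chemistry import SoilChemistryRecord, derive

record = SoilChemistryRecord(
    group="A. sisalana", pH_water=6.67, pH_KCl=5.36,
    OM=37.5, TN=2905.0, P=12.2,
    Ca=269.5, Mg=142.1, K=3.4, Na=6.3, Al=0.0, PA=34.8,
)

d = derive(record)
print(f"TOC = {d['TOC']:.2f} g/kg (from OM {record.OM} via the Van Bemmelen factor)")
print(f"molar ratios: C:N = {d['CS_NS']:.1f}, C:P = {d['CS_PS']:.0f}, N:P = {d['NS_PS']:.0f}")
print(f"SB = {d['SB']:.1f}, CEC = {d['CEC']:.1f} mmolc/kg, "
      f"V% = {d['V_percent']:.1f}, m% = {d['m_percent']:.1f}")
print("flags:", ", ".join(k for k, v in d["flags"].items() if v))

# Base saturation above 90 % with adequate phosphorus marks this soil as
# suitable for most crops; zero aluminium saturation means no liming
# pressure from exchangeable acidity.
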