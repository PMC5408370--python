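"""Mobile elements: quantify Plasmid/Prophage/Virus loads from alignment
hits (e-value < 1e-7, one hit per read, read-number normalized) and test
the case/control contrast with and without statin blocking.
"""

import numpy as np
import pandas as pd

import pdmeta as m

rng = np.random.default_rng(0)
md = pd.DataFrame(
    {"group": ["case"] * 31 + ["control"] * 28,
     "statin": list(rng.random(31) < 1 / 31) + list(rng.random(28) < 11 / 28)},
    index=[f"p{i}" for i in range(59)],
)

hits = m.generate_mobile_hits(
    md, class_rates={"Plasmid": 0.004, "Prophage": 0.002, "Virus": 0.004},
    total_reads=50_000, virus_effect=0.3, seed=1,
)
profiles = m.quantify_mobile_elements(hits, evalue_threshold=1e-7)
print("median normalized load per class:")
print(profiles.groupby(md["group"]).median().round(5).to_string())

res = m.compare_mobile_elements(profiles, md)["tests"]
print("\nrank tests (case vs control):")
print(res[["p"]].round(6).to_string())

blocked = m.compare_mobile_elements(profiles, md, block="statin")["tests"]
print(f"\nVirus p after blocking statin intake: {blocked.loc['Virus', 'p']:.2e}")
print("The planted 0.3x Virus effect in cases shows up in the Virus class only,")
print("and survives stratification on statin use.")
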