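"""One-off builder for the packaged data files.

Writes src/mpctrace/data/synthetic_compound_library.tsv (222 compounds,
a synthetic stand-in for a mouse metabolome library) and
src/mpctrace/data/profiles.yaml (effect profiles used by the synthetic
data generators).
"""
import numpy as np
import yaml
from pyteomics import mass as ptmass

REAL = [
    ("lactate", "C3H6O3"),
    ("pyruvate", "C3H4O3"),
    ("citrate", "C6H8O7"),
    ("succinate", "C4H6O4"),
    ("fumarate", "C4H4O4"),
    ("malate", "C4H6O5"),
    ("alpha_ketoglutarate", "C5H6O5"),
    ("aspartate", "C4H7NO4"),
    ("glutamate", "C5H9NO4"),
    ("glutamine", "C5H10N2O3"),
    ("gaba", "C4H9NO2"),
    ("naag", "C11H16N2O8"),
    ("creatine", "C4H9N3O2"),
    ("phosphocreatine", "C4H10N3O5P"),
    ("proline", "C5H9NO2"),
    ("glutathione", "C10H17N3O6S"),
    ("alanine", "C3H7NO2"),
    ("serine", "C3H7NO3"),
    ("glycine", "C2H5NO2"),
    ("threonine", "C4H9NO3"),
    ("valine", "C5H11NO2"),
    ("leucine", "C6H13NO2"),
    ("methionine", "C5H11NO2S"),
    ("phenylalanine", "C9H11NO2"),
    ("tyrosine", "C9H11NO3"),
    ("tryptophan", "C11H12N2O2"),
    ("histidine", "C6H9N3O2"),
    ("lysine", "C6H14N2O2"),
    ("arginine", "C6H14N4O2"),
    ("asparagine", "C4H8N2O3"),
    ("cysteine", "C3H7NO2S"),
    ("citrulline", "C6H13N3O3"),
    ("ornithine", "C5H12N2O2"),
    ("taurine", "C2H7NO3S"),
    ("carnitine", "C7H15NO3"),
    ("n_acetylaspartate", "C6H9NO5"),
    ("hypoxanthine", "C5H4N4O"),
    ("xanthine", "C5H4N4O2"),
    ("urate", "C5H4N4O3"),
    ("uracil", "C4H4N2O2"),
    ("cytosine", "C4H5N3O"),
    ("adenine", "C5H5N5"),
    ("guanine", "C5H5N5O"),
    ("inosine", "C10H12N4O5"),
    ("adenosine", "C10H13N5O4"),
    ("guanosine", "C10H13N5O5"),
    ("uridine", "C9H12N2O6"),
    ("cytidine", "C9H13N3O5"),
    ("amp", "C10H14N5O7P"),
    ("adp", "C10H15N5O10P2"),
    ("atp", "C10H16N5O13P3"),
    ("ump", "C9H13N2O9P"),
    ("nad", "C21H27N7O14P2"),
    ("hexose", "C6H12O6"),
    ("glucose_6_phosphate", "C6H13O9P"),
    ("fructose_16_bisphosphate", "C6H14O12P2"),
    ("phosphoenolpyruvate", "C3H5O6P"),
    ("3_phosphoglycerate", "C3H7O7P"),
    ("ribose_5_phosphate", "C5H11O8P"),
    ("glycerol_3_phosphate", "C3H9O6P"),
    ("pantothenate", "C9H17NO5"),
    ("nicotinamide", "C6H6N2O"),
    ("ascorbate", "C6H8O6"),
    ("3_hydroxybutyrate", "C4H8O3"),
    ("acetoacetate", "C4H6O3"),
    ("udp_glucose", "C15H24N2O17P2"),
]

MIN_SEP = 0.0025
rng = np.random.default_rng(20160513)

records = []
masses = []


def try_add(cid, name, formula):
    m = ptmass.calculate_mass(formula=formula)
    dep = m - 1.007276
    if not (50.0 <= dep <= 1000.0):
        return False
    if any(abs(m - x) < MIN_SEP for x in masses):
        return False
    records.append((cid, name, formula, round(m, 6)))
    masses.append(m)
    return True


for name, formula in REAL:
    ok = try_add(name, name.replace("_", " "), formula)
    if not ok:
        print("dropped (collision/out of range):", name)

n_real = len(records)
print("real compounds kept:", n_real)

k = 0
while len(records) < 222:
    c = int(rng.integers(3, 26))
    n = int(rng.integers(0, 5))
    p = int(rng.integers(0, 3)) if rng.random() < 0.2 else 0
    s = 1 if rng.random() < 0.1 else 0
    o = int(rng.integers(1, 13))
    dmax = min(c, 9)
    d = int(rng.integers(0, dmax + 1))
    h = 2 * c + 2 + n - 2 * d - p  # rough valence bookkeeping
    if h < 1:
        continue
    formula = f"C{c}H{h}N{n}O{o}" + (f"P{p}" if p else "") + (f"S{s}" if s else "")
    k += 1
    cid = f"syn_{k:04d}"
    try_add(cid, f"synthetic ion {k:04d}", formula)

print("total:", len(records))

with open("src/mpctrace/data/synthetic_compound_library.tsv", "w") as fh:
    fh.write("compound_id\tname\tformula\tmonoisotopic_mass\n")
    for cid, name, formula, m in records:
        fh.write(f"{cid}\t{name}\t{formula}\t{m:.6f}\n")

# ---------------------------------------------------------------- profiles

named_hits = {
    "lactate": 2.2,
    "pyruvate": 2.0,
    "aspartate": 2.5,
    "malate": 2.0,
    "fumarate": 2.0,
    "citrate": 0.4,
    "glutamine": 0.45,
    "glutamate": 0.45,
    "gaba": 0.45,
    "naag": 2.2,
    "phosphocreatine": 0.35,
    "proline": 2.0,
    "glutathione": 0.5,
}
syn_ids = [r[0] for r in records if r[0].startswith("syn_")]
filler = {}
for i, cid in enumerate(syn_ids[:33]):
    filler[cid] = 2.0 if i % 2 == 0 else 0.5
brain_normal_fc = {**named_hits, **filler}
assert len(brain_normal_fc) == 46

profiles = {
    "paper_mef_targeted": {
        "kind": "targeted",
        "diet": "normal",
        "n_per_group": 3,
        "cv": 0.10,
        "baselines": {
            "2_3_phosphoglycerate": 0.8,
            "phosphoenolpyruvate": 0.3,
            "pyruvate": 2.0,
            "lactate": 20.0,
            "aspartate": 5.0,
            "fumarate": 1.0,
            "malate": 2.5,
            "citrate_isocitrate": 3.0,
            "succinate": 1.5,
            "alpha_ketoglutarate": 0.6,
        },
        "fold_changes": {
            "2_3_phosphoglycerate": 2.0,
            "phosphoenolpyruvate": 2.0,
            "pyruvate": 3.0,
            "lactate": 2.5,
            "aspartate": 4.0,
            "fumarate": 1.8,
            "malate": 2.0,
            "citrate_isocitrate": 0.05,
            "succinate": 1.2,
            "alpha_ketoglutarate": 1.1,
        },
    },
    "paper_brain_normal": {
        "kind": "brain",
        "diet": "normal",
        "n_per_group": 4,
        "cv": 0.10,
        "fold_changes": brain_normal_fc,
    },
    "paper_brain_keto": {
        "kind": "brain",
        "diet": "keto",
        "n_per_group": 4,
        "cv": 0.10,
        "fold_changes": {"lactate": 1.3, "aspartate": 1.3},
    },
    "paper_qpcr": {
        "kind": "qpcr",
        "n_per_group": 4,
        "noise_sd": 0.15,
        "reference_gene": "28S",
        "reference_cq": 15.0,
        "baseline_cq": {"MPC1": 22.0, "MPC2": 21.0},
        "relative_expression": {
            "wt": {"MPC1": 1.0, "MPC2": 1.0},
            "het": {"MPC1": 0.5, "MPC2": 1.0},
            "gt": {"MPC1": 0.05, "MPC2": 1.0},
        },
    },
}

with open("src/mpctrace/data/profiles.yaml", "w") as fh:
    yaml.safe_dump(profiles, fh, sort_keys=True)
print("wrote profiles.yaml")
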