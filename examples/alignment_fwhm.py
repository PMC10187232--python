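"""Chromosome-alignment FWHM on a small synthetic cohort.

Simulates two conditions of metaphase cells — well aligned (spread
σ = 1.2 µm) and misaligned (σ = 2.5 µm, longer spindle) — then runs the
full measurement: pole detection → pole-to-pole kinetochore profile →
internal normalization → Gaussian fit → FWHM and spindle length.
"""

import numpy as np
import pandas as pd

import spindlequant as sq

conditions = {"aligned": (1.2, 12.0), "misaligned": (2.5, 15.0)}
rows = []
for cond, (sigma, length) in conditions.items():
    for i in range(10):
        manifest = sq.BipolarManifest(
            seed=1000 + i if cond == "aligned" else 2000 + i,
            kinetochore_spread_sigma_um=sigma, spindle_length_um=length,
            channels=("poles", "kinetochores"))
        img, mf = sq.simulate_bipolar_cell(manifest)
        poles = sq.detect_poles(img, "poles")
        rec = sq.alignment_metric(img, poles)
        rows.append((cond, f"rep{i % 3}", f"{cond}_{i}",
                     rec["fwhm_um"], rec["spindle_length_um"],
                     rec["r_squared"]))

df = pd.DataFrame(rows, columns=["condition", "replicate", "cell_id",
                                 "fwhm_um", "spindle_length_um", "r2"])
print(df.groupby("condition")[["fwhm_um", "spindle_length_um"]]
        .agg(["mean", "std"]).round(2))
print()

# the FWHM of a Gaussian spread sigma is 2*sqrt(2 ln2)*sigma = 2.355*sigma:
# expect ~2.8 um for the aligned and ~5.9 um for the misaligned cohort
table = df.melt(id_vars=["condition", "replicate", "cell_id"],
                value_vars=["fwhm_um"], var_name="metric")
report = sq.compare_groups(table, "fwhm_um", family="parametric")
print("one-way ANOVA p =", f"{report.omnibus_p:.2e}")
print(report.pairwise.to_string(index=False))
print("\nA larger FWHM means kinetochore fluorescence spreads farther from "
      "the metaphase plate, i.e. worse chromosome alignment.")
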