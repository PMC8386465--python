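#!/usr/bin/env python
"""Render the two summary figures from the tables written by the splitting
and lumping analyses: collapse threshold vs rrn copy number per region, and
percent multi-species units vs clustering threshold per region."""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from rrnsplit.pipeline import load_config

cfg = load_config(Path(__file__).parent / "config.yaml")
results = Path(cfg["outdir"]).parent
figdir = results / "figures"
figdir.mkdir(parents=True, exist_ok=True)

collapse = pd.read_csv(results / "splitting" / "collapse_thresholds.tsv", sep="\t")
fig, ax = plt.subplots(figsize=(5, 4))
for region, grp in collapse.groupby("region"):
    grp = grp.sort_values("copy_class")
    ax.plot(grp.copy_class, 100 * grp.median_collapse_threshold, marker="o", label=region)
ax.set_xlabel("rrn copy number")
ax.set_ylabel("threshold for 95% intact genomes (%)")
ax.legend(fontsize=8)
fig.tight_layout()
fig.savefig(figdir / "collapse_threshold_by_copy_number.png", dpi=150)

lump = pd.read_csv(results / "lumping" / "fraction_multi.tsv", sep="\t")
med = lump.groupby(["region", "threshold"], as_index=False).fraction_multi.median()
fig, ax = plt.subplots(figsize=(5, 4))
for region, grp in med.groupby("region"):
    ax.plot(100 * grp.threshold, 100 * grp.fraction_multi, label=region)
for region, grp in lump.groupby("region"):
    ax.axhline(100 * grp.asv_fraction_multi.median(), ls=":", lw=0.8)
ax.set_xlabel("distance threshold (%)")
ax.set_ylabel("OTUs containing >1 species (%)")
ax.legend(fontsize=8)
fig.tight_layout()
fig.savefig(figdir / "multispecies_fraction_by_threshold.png", dpi=150)

print(f"figures under {figdir}/")
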