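#!/usr/bin/env python
"""Step 6: sequence-context analysis of the calls.

Extracts the centered 5-mer around every HS call, classifies it in the
DRACH < NRACN hierarchy, checks the METTL16-like UACAD context and writes
the motif composition and position-frequency matrix.
"""

import argparse
import csv
import json
from pathlib import Path

import numpy as np

from termarrest import Site, SiteSet, call_motifs, motif_composition, read_fasta

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--sim", type=Path, default=Path("results/sim"))
ap.add_argument("--calls", type=Path, default=Path("results/calls_hs.tsv"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

sequences = read_fasta(args.sim / "transcripts.fa")

sites = []
with open(args.calls) as fh:
    header = fh.readline().rstrip("\n").split("\t")
    for line in fh:
        row = dict(zip(header, line.rstrip("\n").split("\t")))
        sites.append(Site(row["reference"], int(row["modified_position"]),
                          row["strand"], name=row["truth_class"]))

calls, skipped = call_motifs(SiteSet(sites), sequences)
comp = motif_composition(calls)

with open(args.out / "motif_calls.tsv", "w", newline="") as fh:
    w = csv.writer(fh, delimiter="\t")
    w.writerow(["reference", "position", "kmer", "category", "mettl16_context"])
    for c in calls:
        w.writerow([c.site.reference, c.site.position, c.kmer,
                    c.category, int(c.mettl16_context)])

summary = {
    "n_classified": len(calls),
    "n_skipped": len(skipped),
    "category_fractions": comp["category_fractions"],
    "top_kmers": comp["top_kmers"],
    "mettl16_fraction": comp["mettl16_fraction"],
    "pfm": np.asarray(comp["pfm"]).tolist(),
}
(args.out / "motif_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
for k in ("n_classified", "category_fractions", "mettl16_fraction", "top_kmers"):
    print(f"  {k}: {summary[k]}")
print(f"wrote {args.out}/motif_calls.tsv, motif_summary.json")
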