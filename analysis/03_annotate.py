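#!/usr/bin/env python
"""Step 3: annotate the call set.

Filters TSS-proximal calls, assigns calls to transcripts, tabulates sites
per transcript and inter-site distances, and measures replicate overlap on
an independently simulated replicate pair.
"""

import argparse
import json
from pathlib import Path

from termarrest import (
    Site,
    SiteSet,
    intersite_distances,
    read_gtf_lite,
    sites_per_transcript,
    tss_filter,
)
from termarrest.experiments import replicate_experiment


def load_calls(path):
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            sites.append(
                Site(row["reference"], int(row["modified_position"]),
                     row["strand"], name=row["truth_class"],
                     score=float(row["delta"]))
            )
    return SiteSet(sites)


ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--sim", type=Path, default=Path("results/sim"))
ap.add_argument("--calls", type=Path, default=Path("results/calls_hs.tsv"))
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

models = read_gtf_lite(args.sim / "transcripts.gtf")
calls = load_calls(args.calls)

internal, excluded, unannotated = tss_filter(calls, models, margin=5)
per_tx = sites_per_transcript(internal, models)
dists = intersite_distances(internal, models)
rep = replicate_experiment(args.seed)

summary = {
    "n_calls": len(calls),
    "n_internal": len(internal),
    "n_tss_excluded": len(excluded),
    "n_unannotated": len(unannotated),
    "sites_per_transcript_histogram": {str(k): v for k, v in sorted(per_tx["histogram"].items())},
    "fraction_single_site_transcripts": per_tx["fraction_single"],
    "median_intersite_distance": (
        sorted(dists["distances"])[len(dists["distances"]) // 2]
        if dists["distances"] else None
    ),
    "replicate_overlap_pct": rep["pct_of_rep1"],
    "replicate_n": [rep["n_rep1"], rep["n_rep2"], rep["n_overlap"]],
}
(args.out / "annotation_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
for k, v in summary.items():
    print(f"  {k}: {v}")
print(f"wrote {args.out}/annotation_summary.json")
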