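#!/usr/bin/env python
"""Step 1: simulate a labeled transcriptome.

Builds a synthetic transcriptome with planted m6A, m5C, Nm and m1A sites,
simulates treated (metabolically labeled) and control pileups, and writes
the sequences, annotation, planted truth and pileup tracks under results/sim
for the downstream steps.
"""

import argparse
from pathlib import Path

from termarrest import (
    SimulationConfig,
    build_transcriptome,
    plant_modifications,
    simulate_pileups,
    truth_to_bed_rows,
    write_bed,
    write_fasta,
    write_gtf_lite,
    write_pileup_tsv,
)

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/sim"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(n_transcripts=40, mean_coverage=60, seed=args.seed)
tx = build_transcriptome(cfg)
truth = plant_modifications(
    tx,
    {"m6A": 30, "m5C": 10, "Nm": 10, "m1A": 6},
    arrest_prob_treated=0.5,
    min_spacing=20,
    seed=args.seed,
)

treated, control = simulate_pileups(tx, truth, cfg)

write_fasta(tx.sequences, args.out / "transcripts.fa")
write_gtf_lite(tx.models, args.out / "transcripts.gtf")
write_bed(truth_to_bed_rows(truth), args.out / "truth.bed")
write_pileup_tsv({"treated": treated, "control": control}, args.out / "pileups.tsv")

print(f"simulated {cfg.n_transcripts} transcripts, {len(truth.entries)} planted sites")
for cls in ("m6A", "m5C", "Nm", "m1A"):
    n = sum(1 for e in truth.entries if e.mod_class == cls)
    print(f"  {cls:4s} {n}")
print(f"wrote {args.out}/transcripts.fa, transcripts.gtf, truth.bed, pileups.tsv")
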