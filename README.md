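# termarrest

Calling, classifying and profiling mRNA methylation sites from reverse-transcription
termination data produced by metabolic labeling experiments.

## Scientific background

Cells fed a propargyl-bearing methionine analog route it through S-adenosyl-methionine
so that methyltransferases install *propargyl* groups instead of methyl groups at their
natural target sites (predominantly m6A and m5C in mRNA). Click chemistry then attaches
a bulky adduct to each propargylated nucleotide, and reverse transcription terminates
when it reaches the adduct. Sequencing the truncated cDNAs turns each modification into
a pileup of read ends: the RT stop is counted exactly **one nucleotide on the
transcript-5′ side** of the modified base, because the polymerase (synthesizing 3′→5′
along the template) stalls before copying it.

Site calling compares a **treated** (labeled) sample against a **control** (normal
methionine) sample at every transcriptome position:

- *arrest rate* = 100 × (reads stopping at the position) / (reads covering it), per sample
- *Δ arrest* = treated rate − control rate, in percentage points
- **high stringency (HS)**: treated coverage > 35 reads and Δ > 20
- **low stringency (LS)**: treated coverage > 20 reads and Δ > 15
- prefilter: ≥ 4 reads summed over both samples; positions at the transcription start
  site (± 5 nt on the transcript-5′ side) are excluded as cap-proximal artifacts.

Passing positions are localized by shifting one nucleotide toward transcript-3′
(plus strand: +1 genomic; minus strand: −1) to name the modified base itself.

Downstream, the package separates modification classes by their **termination
signature** (precise single-position stops for m6A/m5C; stepwise −1/−2 stops for 2′-O
methylation; termination in *both* samples for m1A, which stops RT without labeling),
profiles calls on a scaled **metatranscript axis** (5′UTR → [0,1), CDS → [1,2),
3′UTR → [2,3)), classifies the **sequence context** of each call in the
DRACH ⊂ NRACN motif hierarchy plus the METTL16-like UACAD context, and **attributes**
sites to a methyltransferase by intersecting reproducible in vitro and metabolic call
sets at single-nucleotide resolution.

A seeded simulator generates the whole data chain — transcript models, sequences with
planted motif contexts, per-read RT termination with competing background stops — so
every statistical claim is tested against planted ground truth.

## Worked example

```python
from termarrest import (SimulationConfig, build_transcriptome, TruthEntry, TruthSet,
                        simulate_pileups, call_sites_all, FilterConfig)

cfg = SimulationConfig(n_transcripts=2, mean_coverage=60, seed=7)
tx = build_transcriptome(cfg)
site = tx.drach_anchors["tx0000"][0]          # a planted DRACH context
print("planted m6A at", site, "context", tx.sequences["tx0000"][site-2:site+3])

truth = TruthSet([TruthEntry("tx0000", site, "m6A",
                             arrest_prob_treated=0.5, arrest_prob_control=0.0)])
treated, control = simulate_pileups(tx, truth, cfg)

for r in call_sites_all(treated, control, FilterConfig(tier="HS")):
    print(f"{r.reference}  arrest@{r.arrest_position}  modified@{r.modified_position}  "
          f"rate_t={r.arrest_rate_treated:.1f}  rate_c={r.arrest_rate_control:.1f}  "
          f"delta={r.delta:.1f}  tier={r.tier}")
```

Output:

```
planted m6A at 110 context AGACA
tx0000  arrest@109  modified@110  rate_t=39.1  rate_c=0.0  delta=39.1  tier=HS
```

The single planted site is recovered: the arrest is counted at 109 (one nucleotide 5′
of the modification) and localization names position 110, the planted base, inside its
AGACA (DRACH) context.

## Package layout

| module | contents |
|---|---|
| `termarrest.calling` | arrest rates, Δ scoring, HS/LS filters, localization |
| `termarrest.sim` | transcriptome builder, truth planting, per-read RT simulator |
| `termarrest.io` | pileup TSV, BED6, GTF-lite, FASTA, arrest-table parsing |
| `termarrest.annotate` | TSS filtering, replicate overlap, per-transcript stats |
| `termarrest.signatures` | per-site stop profiles, clustering, precise/stepwise calls |
| `termarrest.metaplot` | cDNA mapping, metatranscript scaling, reflected-KDE density |
| `termarrest.motifs` | DRACH/NRACN classification, METTL16 context, PFMs |
| `termarrest.attribute` | replicate reproducibility and enzyme attribution |
| `termarrest.experiments` | seeded end-to-end benchmark experiments |

The `analysis/` directory holds numbered driver scripts forming a narrative pipeline
(simulate → call → annotate → signatures → metatranscript → motifs → attribute); each
is a thin wrapper around the package that writes tables under `results/`:

```bash
python analysis/01_simulate.py        # writes results/sim/{transcripts.fa,.gtf,truth.bed,pileups.tsv}
python analysis/02_call.py            # HS/LS call tables + precision/recall vs planted truth
python analysis/03_annotate.py        # TSS filter, per-transcript counts, replicate overlap
python analysis/04_signatures.py      # signature clustering of planted site classes
python analysis/05_metatranscript.py  # scaled-axis density of the calls
python analysis/06_motifs.py          # motif composition of the calls
python analysis/07_attribute.py       # in vitro x metabolic attribution
```

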