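"""Synthetic paired treated/control termination pileups with planted truth.

The generator emulates the statistical structure the differential-termination
method assumes: transcripts with 5'UTR/CDS/3'UTR segmentation, modification
sites with sub-stoichiometric per-read arrest probabilities, and i.i.d.
background stops in both samples.  Reads are synthesized in transcript space
(each transcript is its own plus-strand reference), extending from a 3'
start toward 5'; a read crossing a modified position truncates with the
site's arrest probability so that its 5' terminus — the counted arrest
position — is exactly ARREST_OFFSET nt on the 5' side of the modification.

Five signature classes are supported:

* ``m6A`` / ``m5C`` — precise single-offset termination in the treated
  sample only (base-methylation-like; m6A planted inside DRACH motifs).
* ``Nm`` — stepwise termination split between offsets -1 and -2
  (ribose-methylation-like).
* ``m1A`` — strong termination in *both* samples (Watson-Crick face
  methylation blocks RT regardless of labeling).
* ``cap`` — treated-only termination within 5 nt of the transcript 5' end
  (cap-methylation labeling artifact clustered at the TSS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import ARREST_OFFSET, ArrestRecord
from .io import PileupTrack, TrackSet
from .transcripts import TranscriptModel

MOD_CLASSES = ("m6A", "m5C", "Nm", "m1A", "cap")

_DNA = np.array(list("ACGT"))
# IUPAC sets in DNA alphabet for sequence synthesis (internal logic is RNA)
_D, _R, _H = "AGT", "AG", "ACT"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults: 100/300/200 nt UTR5/CDS/UTR3, 150 nt reads, 60x mean coverage
    and a 0.001 per-read per-nt background stop probability (reproducing the
    low but nonzero termination seen in control tracks).
    """

    n_transcripts: int = 20
    utr5_len: int = 100
    cds_len: int = 300
    utr3_len: int = 200
    read_length: int = 150
    mean_coverage: float = 60.0
    background_arrest_prob: float = 0.001
    anchor_spacing: int = 50
    acaga_per_transcript: int = 1
    read_start: str = "uniform"  # or "transcript_end" (unfragmented RT)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_transcripts", "utr5_len", "cds_len", "utr3_len", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cds_len % 3 != 0:
            raise ValueError("cds_len must be divisible by 3")
        if not 0.0 <= self.background_arrest_prob <= 1.0:
            raise ValueError("background_arrest_prob outside [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.read_start not in {"uniform", "transcript_end"}:
            raise ValueError("read_start must be 'uniform' or 'transcript_end'")

    @property
    def transcript_length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len


@dataclass(frozen=True)
class TruthEntry:
    """One planted modification: transcript, 0-based transcript coordinate of
    the modified nucleotide, class, per-sample arrest probabilities and the
    -1 vs -2 signature split (fraction of stops at offset -1)."""

    transcript_id: str
    position: int
    mod_class: str
    arrest_prob_treated: float
    arrest_prob_control: float
    split: float = 1.0


@dataclass
class TruthSet:
    entries: list[TruthEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (e.transcript_id, e.position))
        for e in self.entries:
            if e.mod_class not in MOD_CLASSES:
                raise ValueError(f"unknown class {e.mod_class!r}")
            for p in (e.arrest_prob_treated, e.arrest_prob_control, e.split):
                if not 0.0 <= p <= 1.0:
                    raise ValueError("probability outside [0, 1]")
            if e.mod_class in {"m6A", "m5C"} and e.split != 1.0:
                raise ValueError(f"{e.mod_class} entries must have split 1.0")
            if e.mod_class == "Nm" and not 0.0 < e.split < 1.0:
                raise ValueError("Nm entries must split strictly between -1 and -2")

    def __len__(self) -> int:
        return len(self.entries)

    def by_class(self, *classes: str) -> list[TruthEntry]:
        return [e for e in self.entries if e.mod_class in classes]

    def positions(self, *classes: str) -> set[tuple[str, int]]:
        sel = self.by_class(*classes) if classes else self.entries
        return {(e.transcript_id, e.position) for e in sel}


@dataclass
class Transcriptome:
    """Simulated transcript-space references: one single-exon plus-strand
    model per transcript, its sequence (DNA alphabet, as a genome FASTA
    would store it), and the positions where methylation-context motifs were
    guaranteed during synthesis."""

    models: list[TranscriptModel]
    sequences: dict[str, str]
    drach_anchors: dict[str, list[int]]
    acaga_anchors: dict[str, list[int]]


def build_transcriptome(config: SimulationConfig) -> Transcriptome:
    """Generate ``n_transcripts`` random transcripts with fixed segmentation.

    DRACH 5-mers are written into the CDS/3'UTR at regular spacing (recorded
    anchor centers) so that m6A sites can be planted in-motif; ACAGA 5-mers
    provide non-NRACN contexts for METTL16-like placement.
    """
    rng = np.random.default_rng(config.seed)
    L = config.transcript_length
    models, sequences = [], {}
    drach_anchors: dict[str, list[int]] = {}
    acaga_anchors: dict[str, list[int]] = {}
    for i in range(config.n_transcripts):
        tid = f"tx{i:04d}"
        seq = rng.choice(_DNA, size=L)
        # plant DRACH anchors (center = the A) inside CDS + 3'UTR, clear of ends
        anchors = list(
            range(config.utr5_len + 10, L - 10, config.anchor_spacing)
        )
        for c in anchors:
            motif = [
                rng.choice(list(_D)),
                rng.choice(list(_R)),
                "A",
                "C",
                rng.choice(list(_H)),
            ]
            seq[c - 2 : c + 3] = motif
        # ACAGA anchors between DRACH anchors (center = the first internal A,
        # i.e. position 2 of ACAGA, the methylated A of the METTL16 context)
        acaga = []
        for j in range(config.acaga_per_transcript):
            c = config.utr5_len + 10 + config.anchor_spacing // 2 + j * config.anchor_spacing
            if c + 3 <= L - 10:
                # TACAGA: centered 5-mer ACAGA, full METTL16 UACAD context
                seq[c - 3 : c + 3] = list("TACAGA")
                acaga.append(c)
        models.append(
            TranscriptModel(
                gene_id=f"gene{i:04d}",
                transcript_id=tid,
                reference=tid,
                strand="+",
                exons=[(0, L)],
                cds=(config.utr5_len, config.utr5_len + config.cds_len),
            )
        )
        sequences[tid] = "".join(seq)
        drach_anchors[tid] = anchors
        acaga_anchors[tid] = acaga
    return Transcriptome(models, sequences, drach_anchors, acaga_anchors)


def plant_modifications(
    transcriptome: Transcriptome,
    counts: dict[str, int],
    *,
    arrest_prob_treated: float | dict[str, float] = 0.5,
    arrest_prob_control: float | dict[str, float] | None = None,
    nm_split: float = 0.5,
    min_spacing: int = 10,
    seed: int = 0,
    m6a_context: str = "drach",
) -> TruthSet:
    """Plant the requested number of sites per class, honoring per-class
    invariants and a minimum spacing between sites on the same transcript.

    m6A sites go to DRACH anchors by default (``m6a_context='acaga'`` places
    them in the non-NRACN METTL16-like ACAGA context instead); m5C sites to
    random CDS/3'UTR cytidines; m1A to random adenosines; Nm anywhere
    internal; cap sites within 5 nt of the transcript 5' end.  Raises if a
    class cannot be satisfied, naming the shortfall.
    """
    rng = np.random.default_rng(seed)

    def prob_for(cls: str, which) -> float:
        if isinstance(which, dict):
            return which[cls]
        return which

    used: dict[str, list[int]] = {m.transcript_id: [] for m in transcriptome.models}

    def ok(tid: str, pos: int) -> bool:
        return all(abs(pos - u) >= min_spacing for u in used[tid])

    def take(candidates: list[tuple[str, int]], n: int, cls: str) -> list[tuple[str, int]]:
        order = rng.permutation(len(candidates))
        chosen = []
        for idx in order:
            tid, pos = candidates[idx]
            if ok(tid, pos):
                chosen.append((tid, pos))
                used[tid].append(pos)
                if len(chosen) == n:
                    return chosen
        raise ValueError(
            f"cannot plant {n} {cls} sites: only {len(chosen)} positions available "
            f"(shortfall {n - len(chosen)})"
        )

    entries: list[TruthEntry] = []
    seqs = transcriptome.sequences
    lengths = {tid: len(s) for tid, s in seqs.items()}

    for cls in MOD_CLASSES:
        n = counts.get(cls, 0)
        if n == 0:
            continue
        p_t = prob_for(cls, arrest_prob_treated)
        if arrest_prob_control is None:
            p_c = p_t if cls == "m1A" else 0.0
        else:
            p_c = prob_for(cls, arrest_prob_control)
        if cls == "m6A":
            anchor_map = (
                transcriptome.drach_anchors
                if m6a_context == "drach"
                else transcriptome.acaga_anchors
            )
            candidates = [(tid, c) for tid, cs in anchor_map.items() for c in cs]
        elif cls == "m5C":
            candidates = [
                (tid, p)
                for tid, s in seqs.items()
                for p in range(10, lengths[tid] - 10)
                if s[p] == "C"
            ]
        elif cls == "m1A":
            candidates = [
                (tid, p)
                for tid, s in seqs.items()
                for p in range(10, lengths[tid] - 10)
                if s[p] == "A"
            ]
        elif cls == "Nm":
            candidates = [
                (tid, p) for tid in seqs for p in range(10, lengths[tid] - 10)
            ]
        else:  # cap: <=5 nt from the 5' end, arrest position must stay on-reference
            candidates = [(tid, p) for tid in seqs for p in range(ARREST_OFFSET + 1, 6)]
        split = nm_split if cls == "Nm" else 1.0
        for tid, pos in take(candidates, n, cls):
            entries.append(TruthEntry(tid, pos, cls, p_t, p_c, split))
    return TruthSet(entries)


def _anchor_table(
    truth: TruthSet, treated: bool
) -> dict[str, list[tuple[int, float]]]:
    """Per-transcript list of (stop position, stop probability) anchors."""
    table: dict[str, list[tuple[int, float]]] = {}
    for e in truth.entries:
        p = e.arrest_prob_treated if treated else e.arrest_prob_control
        if p == 0.0:
            continue
        a1 = e.position - ARREST_OFFSET
        anchors = table.setdefault(e.transcript_id, [])
        if e.mod_class == "Nm":
            # independent Bernoulli stops at -1 and -2; stopped reads at -1
            # don't cover -2, giving equal expected *rates* when split=0.5
            anchors.append((a1, p * e.split))
            anchors.append((a1 - 1, p * (1.0 - e.split)))
        else:
            anchors.append((a1, p))
    return table


def simulate_pileups(
    transcriptome: Transcriptome,
    truth: TruthSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[TrackSet, TrackSet]:
    """Sample paired treated/control pileups.

    Reads extend 3'->5'; per covered position a read stops with the
    background probability (both samples) and, at modification anchors, with
    the site's arrest probability (competing risks; the 3'-most event wins).
    A truncated read contributes no coverage 5' of its stop, and one arrest
    at the stop.  Natural 5' ends (read-length exhaustion) are not counted
    as arrests.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    valid = {m.transcript_id for m in transcriptome.models}
    for e in truth.entries:
        if e.transcript_id not in valid:
            raise ValueError(f"truth entry on unknown transcript {e.transcript_id}")
        if not 0 <= e.position - ARREST_OFFSET:
            raise ValueError(f"site at {e.position} leaves no room for the arrest")

    out: list[TrackSet] = []
    for treated in (True, False):
        table = _anchor_table(truth, treated)
        tracks: TrackSet = {}
        for m in transcriptome.models:
            tid = m.transcript_id
            L = len(transcriptome.sequences[tid])
            rl = min(config.read_length, L)
            anchors = sorted(table.get(tid, []), reverse=True)
            bg = config.background_arrest_prob
            if config.read_start == "transcript_end":
                n_reads = int(round(config.mean_coverage))
                starts3 = np.full(n_reads, L - 1)
            else:
                n_reads = int(round(config.mean_coverage * L / rl))
                starts3 = rng.integers(0, L, size=n_reads)
            coverage = np.zeros(L, dtype=np.int64)
            arrest = np.zeros(L, dtype=np.int64)
            bg_offsets = rng.geometric(bg, size=n_reads) if bg > 0 else None
            for r in range(n_reads):
                e3 = int(starts3[r])
                s0 = max(0, e3 - rl + 1)
                stop = -1
                if bg_offsets is not None:
                    p_bg = e3 - (int(bg_offsets[r]) - 1)
                    if p_bg >= s0:
                        stop = p_bg
                for a, p in anchors:
                    # the read meets this anchor only if it crossed the
                    # modification (e3 > a) and would reach it (a >= s0)
                    if a <= stop:
                        break  # anchors sorted 3'->5'; an earlier stop wins
                    if s0 <= a < e3 and rng.random() < p:
                        stop = a
                        break
                if stop >= 0:
                    coverage[stop : e3 + 1] += 1
                    arrest[stop] += 1
                else:
                    coverage[s0 : e3 + 1] += 1
            tracks[(tid, "+")] = PileupTrack(
                reference=tid, strand="+", coverage=coverage, arrest=arrest
            )
        out.append(tracks)
    return out[0], out[1]


def evaluate_calls(
    records: list[ArrestRecord],
    truth: TruthSet,
    classes: tuple[str, ...] = ("m6A", "m5C"),
) -> dict:
    """Precision/recall of called modified positions against the planted
    truth for the detectable (treated-specific) classes."""
    truth_pos = truth.positions(*classes)
    called = {(r.reference, r.modified_position) for r in records}
    tp = len(called & truth_pos)
    fp = len(called - truth_pos)
    fn = len(truth_pos - called)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
    }


def truth_to_bed_rows(truth: TruthSet):
    """Truth entries as Site-like rows for BED export (score = arrest
    probability x 100)."""
    from .annotate import Site

    return [
        Site(
            reference=e.transcript_id,
            position=e.position,
            strand="+",
            name=e.mod_class,
            score=e.arrest_prob_treated * 100.0,
        )
        for e in truth.entries
    ]
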