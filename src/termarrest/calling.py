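"""Differential RT-arrest scoring: the core site-calling statistic.

Reverse transcription proceeds 3'->5' along the RNA template and terminates
when it reaches a bulky modified (clicked) nucleotide.  The counted arrest
position therefore lies exactly one nucleotide on the transcript-5' side of
the modification (ARREST_OFFSET); localization shifts the call one
nucleotide toward transcript-3' to name the modified base itself.

Per position the arrest rate is the percentage of covering reads whose stop
is assigned there; the calling score is the treated-minus-control rate
difference (delta).  Stringency tiers gate on treated coverage and delta
with *exclusive* thresholds: high stringency (HS) coverage > 35 and
delta > 20 percentage points, low stringency (LS) coverage > 20 and
delta > 15.  HS calls are a subset of LS calls by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import PileupTrack, TrackSet

#: nt between the counted arrest position and the modified nucleotide,
#: measured toward transcript-5'.  Shared by the simulator and the caller so
#: localization is exact by construction.
ARREST_OFFSET = 1

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


@dataclass
class FilterConfig:
    """Stringency filter settings.

    Coverage thresholds apply to the treated sample ("sample read coverage
    threshold"); the control enters only through its arrest rate.  Set
    ``coverage_on='both'`` to require the threshold in both samples.  The
    minimal-coverage prefilter (default 4 reads) is summed across samples by
    default (``min_coverage_mode='summed'``) or applied per sample.
    """

    tier: str = "HS"
    min_total_coverage: int = 4
    min_coverage_mode: str = "summed"  # or "per_sample"
    hs_coverage: int = 35
    hs_delta: float = 20.0
    ls_coverage: int = 20
    ls_delta: float = 15.0
    coverage_on: str = "treated"  # or "both"
    tss_margin: int = 5

    def __post_init__(self) -> None:
        if self.tier not in {"HS", "LS"}:
            raise ValueError(f"tier must be HS or LS, got {self.tier!r}")
        if self.hs_coverage < self.ls_coverage or self.hs_delta < self.ls_delta:
            raise ValueError("HS thresholds must be at least as strict as LS")
        if self.min_coverage_mode not in {"summed", "per_sample"}:
            raise ValueError("min_coverage_mode must be 'summed' or 'per_sample'")
        if self.coverage_on not in {"treated", "both"}:
            raise ValueError("coverage_on must be 'treated' or 'both'")


@dataclass
class ArrestRecord:
    """A candidate site: the arrest position with per-sample coverage, rates,
    the delta score, the stringency tier passed and the localized modified
    nucleotide."""

    reference: str
    arrest_position: int
    strand: str
    coverage_treated: int
    coverage_control: int
    arrest_rate_treated: float
    arrest_rate_control: float
    delta: float
    tier: str = "none"
    modified_position: int | None = None
    base: str | None = None


def arrest_rate(arrest_count: int, coverage: int) -> float:
    """Percentage of covering reads whose RT stop is at this position.

    Undefined for zero coverage: raises rather than returning 0, because a
    position with no reads carries no evidence and must be skipped, not
    scored.
    """
    if coverage == 0:
        raise ZeroDivisionError("arrest rate undefined at zero coverage")
    if not 0 <= arrest_count <= coverage:
        raise ValueError(f"arrest count {arrest_count} outside [0, {coverage}]")
    return 100.0 * arrest_count / coverage


def delta_arrest(rate_treated: float, rate_control: float) -> float:
    """Signed difference treated - control, in percentage points."""
    for r in (rate_treated, rate_control):
        if not 0.0 <= r <= 100.0:
            raise ValueError(f"rate {r} outside [0, 100]")
    return rate_treated - rate_control


def _tier(record: ArrestRecord, config: FilterConfig) -> str:
    cov = record.coverage_treated
    if config.coverage_on == "both":
        cov = min(record.coverage_treated, record.coverage_control)
    if cov > config.hs_coverage and record.delta > config.hs_delta:
        return "HS"
    if cov > config.ls_coverage and record.delta > config.ls_delta:
        return "LS"
    return "none"


def apply_filters(records: list[ArrestRecord], config: FilterConfig) -> list[ArrestRecord]:
    """Assign tiers and keep records passing the configured stringency."""
    out = []
    for rec in records:
        tier = _tier(rec, config)
        if tier == "HS" or (tier == "LS" and config.tier == "LS"):
            out.append(replace(rec, tier=tier))
    return out


def call_sites(
    treated: PileupTrack, control: PileupTrack, config: FilterConfig | None = None
) -> list[ArrestRecord]:
    """Score one aligned treated/control track pair and return passing,
    localized records sorted by position."""
    if config is None:
        config = FilterConfig()
    if len(treated) != len(control):
        raise ValueError("treated and control tracks differ in length")
    if treated.reference != control.reference or treated.strand != control.strand:
        raise ValueError("treated and control tracks are not aligned")

    cov_t, cov_c = treated.coverage, control.coverage
    if config.min_coverage_mode == "summed":
        prefilter = (cov_t + cov_c) >= config.min_total_coverage
    else:
        prefilter = (cov_t >= config.min_total_coverage) & (
            cov_c >= config.min_total_coverage
        )
    # rate is undefined at zero coverage in either sample: skip, don't score
    candidate = prefilter & (cov_t > 0) & (cov_c > 0)

    records: list[ArrestRecord] = []
    for pos in np.flatnonzero(candidate):
        rate_t = arrest_rate(int(treated.arrest[pos]), int(cov_t[pos]))
        rate_c = arrest_rate(int(control.arrest[pos]), int(cov_c[pos]))
        rec = ArrestRecord(
            reference=treated.reference,
            arrest_position=int(pos),
            strand=treated.strand,
            coverage_treated=int(cov_t[pos]),
            coverage_control=int(cov_c[pos]),
            arrest_rate_treated=rate_t,
            arrest_rate_control=rate_c,
            delta=delta_arrest(rate_t, rate_c),
        )
        tier = _tier(rec, config)
        if tier == "HS" or (tier == "LS" and config.tier == "LS"):
            rec.tier = tier
            try:
                rec.modified_position = localize_modification(
                    rec, reference_length=len(treated)
                )
            except IndexError:
                # arrest at the reference edge: no 3' neighbor to attribute
                continue
            records.append(rec)
    return records


def call_sites_all(
    treated: TrackSet, control: TrackSet, config: FilterConfig | None = None
) -> list[ArrestRecord]:
    """Run :func:`call_sites` over every (reference, strand) shared by both
    samples, sorted by reference then position."""
    records: list[ArrestRecord] = []
    for key in sorted(set(treated) & set(control)):
        records.extend(call_sites(treated[key], control[key], config))
    return sorted(records, key=lambda r: (r.reference, r.arrest_position))


def localize_modification(
    record: ArrestRecord, reference_length: int | None = None
) -> int:
    """0-based position of the modified nucleotide: the arrest position
    shifted ARREST_OFFSET nt toward transcript-3' (plus strand: +1 genomic,
    minus strand: -1 genomic)."""
    shift = ARREST_OFFSET if record.strand == "+" else -ARREST_OFFSET
    pos = record.arrest_position + shift
    if pos < 0 or (reference_length is not None and pos >= reference_length):
        raise IndexError(
            f"localized position {pos} off reference (length {reference_length})"
        )
    return pos


def expected_arrest_position(modified_position: int, strand: str) -> int:
    """Inverse of :func:`localize_modification`: where a stop induced by a
    modification at this position is counted."""
    shift = ARREST_OFFSET if strand == "+" else -ARREST_OFFSET
    return modified_position - shift


def assign_base(
    records: list[ArrestRecord], sequences: dict[str, str]
) -> tuple[list[ArrestRecord], dict[str, float]]:
    """Annotate each record with the transcript-orientation base (RNA
    alphabet) at its modified position and tabulate the composition.

    Minus-strand records report the complement of the genomic base.
    Fractions sum to 1 over {A, C, G, U} (plus N if present).
    """
    annotated = []
    counts: dict[str, int] = {}
    for rec in records:
        seq = sequences[rec.reference]
        pos = rec.modified_position
        if pos is None:
            pos = localize_modification(rec, reference_length=len(seq))
        if not 0 <= pos < len(seq):
            raise IndexError(f"position {pos} beyond sequence {rec.reference}")
        base = seq[pos].upper()
        if rec.strand == "-":
            base = _COMPLEMENT.get(base, "N")
        base = "U" if base == "T" else base
        annotated.append(replace(rec, modified_position=pos, base=base))
        counts[base] = counts.get(base, 0) + 1
    total = sum(counts.values())
    composition = {b: c / total for b, c in sorted(counts.items())} if total else {}
    return annotated, composition


# -- read-level construction ----------------------------------------------


def pileup_from_reads(
    reads: list[tuple[int, int, bool]],
    length: int,
    reference: str = "ref",
    strand: str = "+",
) -> PileupTrack:
    """Build a pileup track from explicit reads.

    Each read is ``(five_prime, three_prime, arrested)`` with both ends
    0-based inclusive in transcript coordinates; an arrested read contributes
    one arrest at its transcript-5' terminus and one coverage unit at every
    covered position including the terminus (this makes arrest <= coverage
    structural).
    """
    coverage = np.zeros(length, dtype=np.int64)
    arrest = np.zeros(length, dtype=np.int64)
    for five, three, stopped in reads:
        if not (0 <= five <= three < length):
            raise ValueError(f"read ({five}, {three}) outside [0, {length})")
        coverage[five : three + 1] += 1
        if stopped:
            arrest[five] += 1
    return PileupTrack(reference=reference, strand=strand, coverage=coverage, arrest=arrest)
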