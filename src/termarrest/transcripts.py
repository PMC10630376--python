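"""Transcript models and strand-aware genome/transcript coordinate arithmetic.

All internal coordinates are 0-based half-open; conversion to 1-based
conventions (GTF) happens only at the I/O boundary.  cDNA coordinates run
5'->3' along the spliced transcript, so position 0 is the transcription
start site (TSS) on either strand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field


@dataclass
class TranscriptModel:
    """A spliced transcript with optional CDS.

    Parameters
    ----------
    gene_id, transcript_id : str
        Locus and transcript identifiers (GTF attributes).
    reference : str
        Chromosome / contig name.
    strand : str
        '+' or '-'.
    exons : list of (start, end)
        Genomic exon intervals, 0-based half-open.  Stored sorted by start;
        they must not overlap.
    cds : (start, end) or None
        Genomic CDS span (0-based half-open), None for non-coding.
    """

    gene_id: str
    transcript_id: str
    reference: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    _starts: list[int] = field(init=False, repr=False)
    _offsets: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon ({s}, {e}) in {self.transcript_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if ce <= cs:
                raise ValueError(f"empty CDS in {self.transcript_id}")
            covered = sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)
            span_in_exons = any(s <= cs < e for s, e in self.exons) and any(
                s < ce <= e for s, e in self.exons
            )
            if not span_in_exons or covered == 0:
                raise ValueError(f"CDS outside exons in {self.transcript_id}")
        # cumulative spliced offsets in genomic (plus-strand) order
        self._starts = [s for s, _ in self.exons]
        self._offsets = []
        acc = 0
        for s, e in self.exons:
            self._offsets.append(acc)
            acc += e - s

    # -- derived geometry -------------------------------------------------

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Genomic position of the transcript 5' end (cDNA position 0)."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def cds_len(self) -> int:
        if self.cds is None:
            return 0
        cs, ce = self.cds
        return sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)

    @property
    def utr5_len(self) -> int:
        if self.cds is None:
            return 0
        cs, ce = self.cds
        first_cds = cs if self.strand == "+" else ce - 1
        pos = self.genomic_to_cdna(first_cds)
        assert pos is not None
        return pos

    @property
    def utr3_len(self) -> int:
        if self.cds is None:
            return 0
        return self.spliced_length - self.utr5_len - self.cds_len

    # -- coordinate mapping -----------------------------------------------

    def _plus_cdna(self, gpos: int) -> int | None:
        i = bisect.bisect_right(self._starts, gpos) - 1
        if i < 0:
            return None
        s, e = self.exons[i]
        if gpos >= e:
            return None
        return self._offsets[i] + (gpos - s)

    def genomic_to_cdna(self, gpos: int) -> int | None:
        """Map a genomic position to its cDNA coordinate, or None if intronic
        or outside the transcript."""
        plus = self._plus_cdna(gpos)
        if plus is None:
            return None
        if self.strand == "+":
            return plus
        return self.spliced_length - 1 - plus

    def cdna_to_genomic(self, cpos: int) -> int:
        """Inverse of :meth:`genomic_to_cdna` (exonic positions only)."""
        n = self.spliced_length
        if not 0 <= cpos < n:
            raise ValueError(f"cDNA position {cpos} outside [0, {n})")
        plus = cpos if self.strand == "+" else n - 1 - cpos
        i = bisect.bisect_right(self._offsets, plus) - 1
        s, _ = self.exons[i]
        return s + (plus - self._offsets[i])

    def contains(self, gpos: int) -> bool:
        return self._plus_cdna(gpos) is not None


def longest_per_locus(models: list[TranscriptModel]) -> dict[str, TranscriptModel]:
    """Pick one transcript per gene locus: maximal spliced length, ties broken
    by lexicographic transcript id (deterministic)."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.spliced_length > cur.spliced_length
            or (m.spliced_length == cur.spliced_length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return best


def assign_to_transcript(
    reference: str, gpos: int, strand: str, models: list[TranscriptModel]
) -> TranscriptModel | None:
    """Find the transcript a site belongs to: among same-reference, same-strand
    transcripts containing the position, the longest per locus wins; across
    loci, the overall longest (ties by transcript id)."""
    hits = [
        m
        for m in models
        if m.reference == reference and m.strand == strand and m.contains(gpos)
    ]
    if not hits:
        return None
    per_locus = longest_per_locus(hits)
    return min(
        per_locus.values(), key=lambda m: (-m.spliced_length, m.transcript_id)
    )
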