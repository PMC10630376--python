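"""Readers and writers for the on-disk formats the pipeline touches.

Formats: the bespoke pileup TSV (canonical pipeline input, documented in the
README), BED6 site lists, a GTF subset ("GTF-lite": exon and CDS features
only) and FASTA.  Internal coordinates are 0-based half-open everywhere;
GTF's 1-based inclusive convention is converted exactly at this boundary.

Readers reject records violating type invariants (negative counts,
arrest > coverage, end <= start) with the offending line number rather than
silently clamping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import Site
from .transcripts import TranscriptModel


class ParseError(ValueError):
    """Malformed record in an input file; message carries the line number."""


@dataclass
class PileupTrack:
    """Per-position read coverage and arrest counts for one sample over one
    reference strand.

    ``coverage[i]`` counts reads covering position i; ``arrest[i]`` counts
    reads whose reverse-transcription stop is assigned to position i.
    Positions are 0-based and contiguous from 0.
    """

    reference: str
    strand: str
    coverage: np.ndarray
    arrest: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.arrest = np.asarray(self.arrest, dtype=np.int64)
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.coverage.shape != self.arrest.shape:
            raise ValueError("coverage and arrest arrays differ in length")
        if (self.coverage < 0).any() or (self.arrest < 0).any():
            raise ValueError("negative counts in pileup track")
        if (self.arrest > self.coverage).any():
            bad = int(np.argmax(self.arrest > self.coverage))
            raise ValueError(f"arrest > coverage at position {bad}")

    def __len__(self) -> int:
        return len(self.coverage)


# a sample's tracks, keyed by (reference, strand)
TrackSet = dict[tuple[str, str], PileupTrack]

_PILEUP_HEADER = ["reference", "position", "strand", "coverage", "arrest", "sample"]


def write_pileup_tsv(tracks: dict[str, TrackSet], path: str | Path) -> None:
    """Write pileup tracks for one or more samples to a TSV file.

    ``tracks`` maps sample name -> {(reference, strand): PileupTrack}.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_PILEUP_HEADER) + "\n")
        for sample in sorted(tracks):
            for (ref, strand), tr in sorted(tracks[sample].items()):
                for pos in range(len(tr)):
                    fh.write(
                        f"{ref}\t{pos}\t{strand}\t{tr.coverage[pos]}\t"
                        f"{tr.arrest[pos]}\t{sample}\n"
                    )


def read_pileup_tsv(path: str | Path, strict: bool = True) -> dict[str, TrackSet]:
    """Read a pileup TSV back into per-sample track sets.

    Positions must be contiguous from 0 per (sample, reference, strand).
    Violations (arrest > coverage, negative counts, malformed lines) raise
    :class:`ParseError` naming the line.
    """
    buf: dict[tuple[str, str, str], list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_PILEUP_HEADER)] != _PILEUP_HEADER:
            if strict and header != _PILEUP_HEADER:
                raise ParseError(f"line 1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"line {lineno}: expected 6 columns, got {len(fields)}")
            ref, pos_s, strand, cov_s, arr_s, sample = fields[:6]
            try:
                pos, cov, arr = int(pos_s), int(cov_s), int(arr_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer field ({exc})") from None
            if cov < 0 or arr < 0:
                raise ParseError(f"line {lineno}: negative count")
            if arr > cov:
                raise ParseError(f"line {lineno}: arrest {arr} exceeds coverage {cov}")
            if strand not in {"+", "-"}:
                raise ParseError(f"line {lineno}: invalid strand {strand!r}")
            buf.setdefault((sample, ref, strand), []).append((pos, cov, arr))

    out: dict[str, TrackSet] = {}
    for (sample, ref, strand), rows in buf.items():
        rows.sort()
        positions = [r[0] for r in rows]
        if positions != list(range(len(rows))):
            raise ParseError(
                f"non-contiguous positions for sample={sample} reference={ref}"
            )
        out.setdefault(sample, {})[(ref, strand)] = PileupTrack(
            reference=ref,
            strand=strand,
            coverage=np.array([r[1] for r in rows]),
            arrest=np.array([r[2] for r in rows]),
        )
    return out


# -- BED6 -----------------------------------------------------------------


def write_bed(sites, path: str | Path) -> None:
    """Write sites as BED6 (0-based half-open, 1-nt intervals)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.reference}\t{s.position}\t{s.position + 1}\t{s.name}\t"
                f"{s.score:g}\t{s.strand}\n"
            )


def read_bed(path: str | Path) -> list[Site]:
    """Read BED6 site records.  Strand '.' is rejected: called sites are
    strand-specific by construction."""
    sites: list[Site] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"line {lineno}: BED6 requires 6 columns")
            ref, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                score = float(score_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            if end <= start:
                raise ParseError(f"line {lineno}: end {end} <= start {start}")
            if strand not in {"+", "-"}:
                raise ParseError(f"line {lineno}: site records must be stranded")
            sites.append(Site(ref, start, strand, name=name, score=score))
    return sites


# -- GTF-lite -------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_lite(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF restricted to exon and CDS features.

    GTF coordinates are 1-based inclusive; models store 0-based half-open
    intervals.  A CDS falling outside the exon union raises a validation
    error (from :class:`TranscriptModel`).
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: expected 9 GTF columns")
            ref, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature not in {"exon", "CDS"}:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if end < start:
                raise ParseError(f"line {lineno}: end < start")
            attr = dict(_ATTR_RE.findall(attrs))
            try:
                gid, tid = attr["gene_id"], attr["transcript_id"]
            except KeyError:
                raise ParseError(f"line {lineno}: missing gene_id/transcript_id") from None
            iv = (start - 1, end)  # to 0-based half-open
            meta.setdefault(tid, (gid, ref, strand))
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    models = []
    for tid, (gid, ref, strand) in meta.items():
        if tid not in exons:
            raise ParseError(f"transcript {tid} has CDS but no exons")
        cds_iv = None
        if tid in cds:
            parts = cds[tid]
            cds_iv = (min(s for s, _ in parts), max(e for _, e in parts))
        models.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=tid,
                reference=ref,
                strand=strand,
                exons=exons[tid],
                cds=cds_iv,
            )
        )
    return sorted(models, key=lambda m: m.transcript_id)


def write_gtf_lite(models: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.reference}\ttermarrest\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds is not None:
                cs, ce = m.cds
                for s, e in m.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if oe > os_:
                        fh.write(
                            f"{m.reference}\ttermarrest\tCDS\t{os_ + 1}\t{oe}\t.\t"
                            f"{m.strand}\t.\t{attrs}\n"
                        )


# -- FASTA ----------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- external arrest tables ----------------------------------------------


def parse_jacusa_arrest_table(path: str | Path):
    """Parse a tab-separated differential-arrest table into candidate records.

    Expected columns: reference, position (0-based), strand,
    coverage_treated, coverage_control, arrest_rate_treated,
    arrest_rate_control — rates on the 0-100 percent scale.  This is the
    interchange point for externally computed per-site termination tables
    (e.g. an rt-arrest run exported to TSV); the resulting candidates feed
    the same stringency filters as the internal pileup path.
    """
    from .calling import ArrestRecord, delta_arrest

    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = [
            "reference",
            "position",
            "strand",
            "coverage_treated",
            "coverage_control",
            "arrest_rate_treated",
            "arrest_rate_control",
        ]
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(f"missing columns: {missing}")
        idx = {c: header.index(c) for c in required}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                pos = int(fields[idx["position"]])
                cov_t = int(fields[idx["coverage_treated"]])
                cov_c = int(fields[idx["coverage_control"]])
                rate_t = float(fields[idx["arrest_rate_treated"]])
                rate_c = float(fields[idx["arrest_rate_control"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            for rate in (rate_t, rate_c):
                if not 0.0 <= rate <= 100.0:
                    raise ParseError(f"line {lineno}: rate {rate} outside [0, 100]")
            if cov_t < 0 or cov_c < 0:
                raise ParseError(f"line {lineno}: negative coverage")
            records.append(
                ArrestRecord(
                    reference=fields[idx["reference"]],
                    arrest_position=pos,
                    strand=fields[idx["strand"]],
                    coverage_treated=cov_t,
                    coverage_control=cov_c,
                    arrest_rate_treated=rate_t,
                    arrest_rate_control=rate_c,
                    delta=delta_arrest(rate_t, rate_c),
                )
            )
    return records
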