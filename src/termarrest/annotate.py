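"""Site collections and site-level statistics.

Covers TSS-proximity filtering (cap-labeling artifacts), replicate
reproducibility, per-transcript site counts and inter-site distances.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .transcripts import TranscriptModel, assign_to_transcript


@dataclass(frozen=True)
class Site:
    """A single modified-nucleotide call: reference, 0-based position of the
    modified nucleotide, and strand."""

    reference: str
    position: int
    strand: str
    name: str = "site"
    score: float = 0.0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.reference, self.position, self.strand)


@dataclass
class SiteSet:
    """A deduplicated set of sites with optional per-site attributes."""

    sites: list[Site] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple, Site] = {}
        for s in self.sites:
            seen.setdefault(s.key, s)
        self.sites = sorted(seen.values(), key=lambda s: s.key)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def keys(self) -> set[tuple[str, int, str]]:
        return {s.key for s in self.sites}

    def intersection(self, other: "SiteSet") -> "SiteSet":
        common = self.keys() & other.keys()
        return SiteSet([s for s in self.sites if s.key in common])


def tss_filter(
    sites: SiteSet,
    transcripts: list[TranscriptModel],
    margin: int = 5,
) -> tuple[SiteSet, SiteSet, list[Site]]:
    """Split sites into internal vs TSS-proximal.

    Cap methylation is metabolically labeled too, so terminations within
    ``margin`` nt of a transcription start site are treated as cap artifacts
    and excluded from internal-site analysis.  The distance is measured from
    the site to the nearest TSS in the transcript-5' direction, on the same
    reference and strand (one-sided; a TSS downstream of the site never
    excludes it).

    Returns ``(internal, excluded, unannotated)`` where *unannotated* lists
    sites on references without any same-strand transcript (these are kept in
    *internal* but flagged here).  ``|internal| + |excluded| == |input|``.
    """
    by_ref: dict[tuple[str, str], list[int]] = {}
    for m in transcripts:
        by_ref.setdefault((m.reference, m.strand), []).append(m.tss)

    internal: list[Site] = []
    excluded: list[Site] = []
    unannotated: list[Site] = []
    for s in sites:
        tss_list = by_ref.get((s.reference, s.strand))
        if not tss_list:
            internal.append(s)
            unannotated.append(s)
            continue
        if s.strand == "+":
            dists = [s.position - t for t in tss_list if t <= s.position]
        else:
            dists = [t - s.position for t in tss_list if t >= s.position]
        if dists and min(dists) <= margin:
            excluded.append(s)
        else:
            internal.append(s)
    return SiteSet(internal), SiteSet(excluded), unannotated


def replicate_overlap(rep1: SiteSet, rep2: SiteSet) -> dict:
    """Exact (reference, position, strand) overlap between two replicate call
    sets, with the per-replicate fractions reported in percent."""
    inter = rep1.keys() & rep2.keys()
    n = len(inter)
    return {
        "n_rep1": len(rep1),
        "n_rep2": len(rep2),
        "n_overlap": n,
        "pct_of_rep1": 100.0 * n / len(rep1) if len(rep1) else 0.0,
        "pct_of_rep2": 100.0 * n / len(rep2) if len(rep2) else 0.0,
    }


def _site_transcript(site: Site, transcripts: list[TranscriptModel]):
    return assign_to_transcript(site.reference, site.position, site.strand, transcripts)


def sites_per_transcript(
    sites: SiteSet, transcripts: list[TranscriptModel]
) -> dict:
    """Histogram of modification counts per transcript.

    Sites are assigned to the longest transcript per locus (the same rule the
    metatranscript profile uses, keeping the figures consistent).  Returns the
    histogram over counts 1, 2, ... and the fraction of modified transcripts
    carrying exactly one site.
    """
    counts: Counter[str] = Counter()
    for s in sites:
        m = _site_transcript(s, transcripts)
        if m is not None:
            counts[m.transcript_id] += 1
    hist = Counter(counts.values())
    n_tx = sum(hist.values())
    return {
        "histogram": dict(sorted(hist.items())),
        "n_transcripts": n_tx,
        "fraction_single": hist.get(1, 0) / n_tx if n_tx else 0.0,
    }


def intersite_distances(
    sites: SiteSet,
    transcripts: list[TranscriptModel],
    cutoff: int = 1000,
) -> dict:
    """Distances between neighboring sites on the same transcript.

    Sites are mapped to cDNA coordinates on their assigned transcript and the
    distances between consecutive sorted positions computed.  Distances above
    ``cutoff`` are excluded from the histogram but counted separately (the
    profile is dominated by short-range clustering, so the tail is truncated
    for display).
    """
    per_tx: dict[str, list[int]] = {}
    for s in sites:
        m = _site_transcript(s, transcripts)
        if m is None:
            continue
        cpos = m.genomic_to_cdna(s.position)
        if cpos is not None:
            per_tx.setdefault(m.transcript_id, []).append(cpos)
    within: list[int] = []
    n_beyond = 0
    for positions in per_tx.values():
        positions.sort()
        for a, b in zip(positions, positions[1:]):
            d = b - a
            if d <= cutoff:
                within.append(d)
            else:
                n_beyond += 1
    return {"distances": within, "n_beyond_cutoff": n_beyond}
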