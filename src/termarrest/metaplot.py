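"""Metatranscript (metagene) profiling of called sites.

Sites are mapped to cDNA coordinates on the longest protein-coding
transcript per locus, rescaled so the 5'UTR spans [0,1), the CDS [1,2) and
the 3'UTR [2,3), and summarized as a kernel density on [0,3).  The scaled
axis makes transcripts of different lengths comparable; the CDS/3'UTR
boundary at 2.0 is where stop-codon-proximal enrichment shows up.
"""

from __future__ import annotations

import numpy as np

from .annotate import Site, SiteSet
from .transcripts import TranscriptModel, assign_to_transcript


def genomic_to_cdna(
    site: Site, transcripts: list[TranscriptModel]
) -> tuple[str, int] | None:
    """Map a genomic site to (transcript id, cDNA position) through the
    spliced coordinates of the longest same-strand transcript containing it;
    intronic/intergenic sites return None (unmapped is a category, not an
    error)."""
    m = assign_to_transcript(site.reference, site.position, site.strand, transcripts)
    if m is None:
        return None
    cpos = m.genomic_to_cdna(site.position)
    if cpos is None:
        return None
    return m.transcript_id, cpos


def metacoordinate(
    cdna_position: int, utr5_len: int, cds_len: int, utr3_len: int
) -> float:
    """Rescale a cDNA position into the [0,3) metatranscript axis.

    Within each segment the position is divided by the segment length and
    offset by 0/1/2, so segment boundaries map exactly: the first CDS base
    to 1.0, the first 3'UTR base to 2.0.  Requires all three segments to be
    non-empty (non-coding transcripts are excluded from the profile).
    """
    total = utr5_len + cds_len + utr3_len
    if min(utr5_len, cds_len, utr3_len) <= 0:
        raise ValueError("metatranscript axis requires non-empty UTR5/CDS/UTR3")
    if not 0 <= cdna_position < total:
        raise ValueError(f"cDNA position {cdna_position} outside [0, {total})")
    if cdna_position < utr5_len:
        return cdna_position / utr5_len
    if cdna_position < utr5_len + cds_len:
        return 1.0 + (cdna_position - utr5_len) / cds_len
    return 2.0 + (cdna_position - utr5_len - cds_len) / utr3_len


def scaled_coordinates(
    sites: SiteSet, transcripts: list[TranscriptModel]
) -> tuple[np.ndarray, list[tuple[Site, str]]]:
    """Scaled metatranscript coordinates for every mappable site; unmappable
    sites (intronic, non-coding transcript, empty segment) are returned with
    a reason."""
    by_id = {m.transcript_id: m for m in transcripts}
    coords, skipped = [], []
    for s in sites:
        mapped = genomic_to_cdna(s, transcripts)
        if mapped is None:
            skipped.append((s, "unmapped"))
            continue
        tid, cpos = mapped
        m = by_id[tid]
        if m.cds is None:
            skipped.append((s, "non-coding transcript"))
            continue
        try:
            coords.append(metacoordinate(cpos, m.utr5_len, m.cds_len, m.utr3_len))
        except ValueError as exc:
            skipped.append((s, str(exc)))
    return np.asarray(coords, dtype=float), skipped


def density_profile(
    coords: np.ndarray,
    bandwidth: float = 0.05,
    grid_size: int = 601,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of scaled coordinates on [0, 3).

    Boundary mass is reflected at 0 and 3 so the density integrates to 1
    over the metatranscript axis.  Bandwidth is in scaled units (default
    0.05, i.e. 5% of a segment).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("density of empty coordinate set is undefined")
    if ((coords < 0) | (coords >= 3)).any():
        raise ValueError("scaled coordinates must lie in [0, 3)")
    grid = np.linspace(0.0, 3.0, grid_size)
    h = bandwidth
    # reflect about both boundaries: x -> -x and x -> 6-x
    sources = np.concatenate([coords, -coords, 6.0 - coords])
    diff = (grid[:, None] - sources[None, :]) / h
    dens = np.exp(-0.5 * diff**2).sum(axis=1) / (
        coords.size * h * np.sqrt(2.0 * np.pi)
    )
    return grid, dens
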