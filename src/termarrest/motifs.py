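"""Sequence-context extraction and hierarchical consensus-motif calling.

m6A writers leave a sequence fingerprint: METTL3-14 methylates within the
DRACH consensus (D = A/G/U, R = A/G, H = A/C/U), a superset relation holds
with NRACN (N = any), and METTL16 targets a UACAD context whose core reads
ACAGA on the transcript.  5-mers centered on called adenosines are
classified into the mutually exclusive hierarchy
DRACH -> NRACN (non-DRACH) -> non-NRACN.

All sequence logic runs in the RNA alphabet; DNA is accepted at the I/O
boundary and converted (T -> U, minus-strand reverse complement).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .annotate import Site

IUPAC_RNA = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "U": {"U"},
    "R": {"A", "G"},
    "Y": {"C", "U"},
    "D": {"A", "G", "U"},
    "H": {"A", "C", "U"},
    "N": {"A", "C", "G", "U"},
}

DRACH = "DRACH"
NRACN = "NRACN"
METTL16_CONTEXT = "UACAD"  # modified A at the fourth position

CATEGORIES = ("DRACH", "NRACN_non_DRACH", "non_NRACN")

_RC_DNA = str.maketrans("ACGTUN", "TGCAAN")


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def matches(kmer: str, pattern: str) -> bool:
    """IUPAC pattern match in the RNA alphabet."""
    if len(kmer) != len(pattern):
        return False
    return all(b in IUPAC_RNA[p] for b, p in zip(_to_rna(kmer), pattern))


@dataclass(frozen=True)
class MotifCall:
    site: Site
    kmer: str
    category: str
    mettl16_context: bool = False


def extract_kmer(site: Site, sequences: dict[str, str], k: int = 5) -> str:
    """Transcript-orientation k-mer centered on the modified nucleotide.

    Minus-strand sites are reverse-complemented; output is RNA alphabet.
    Raises ``ValueError`` when the window runs off the sequence end (callers
    skip such sites with the reason).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    half = k // 2
    seq = sequences[site.reference]
    lo, hi = site.position - half, site.position + half + 1
    if lo < 0 or hi > len(seq):
        raise ValueError(f"{k}-mer window around {site.position} off sequence end")
    window = seq[lo:hi].upper()
    if site.strand == "-":
        window = window.translate(_RC_DNA)[::-1]
    return _to_rna(window)


def classify_motif(kmer: str) -> str:
    """Hierarchical category of a 5-mer with central A: DRACH, else NRACN
    (non-DRACH), else non-NRACN."""
    kmer = _to_rna(kmer)
    if len(kmer) != 5:
        raise ValueError(f"expected a 5-mer, got {kmer!r}")
    if kmer[2] != "A":
        raise ValueError(f"central base of {kmer!r} is not A; the motif "
                         "hierarchy is defined for adenosine sites")
    if matches(kmer, DRACH):
        return "DRACH"
    if matches(kmer, NRACN):
        return "NRACN_non_DRACH"
    return "non_NRACN"


def mettl16_context(site: Site, sequences: dict[str, str]) -> bool:
    """True iff the [-3, +1] window around the modified A matches the
    METTL16 consensus UACAD (modified A fourth); False with an off-end
    window."""
    seq = sequences[site.reference]
    if site.strand == "+":
        lo, hi = site.position - 3, site.position + 2
        if lo < 0 or hi > len(seq):
            return False
        window = seq[lo:hi].upper()
    else:
        lo, hi = site.position - 1, site.position + 4
        if lo < 0 or hi > len(seq):
            return False
        window = seq[lo:hi].upper().translate(_RC_DNA)[::-1]
    return matches(_to_rna(window), METTL16_CONTEXT)


def call_motifs(
    sites, sequences: dict[str, str], k: int = 5
) -> tuple[list[MotifCall], list[tuple[Site, str]]]:
    """Classify every A-centered site; non-A sites and off-end windows are
    skipped with the reason."""
    calls, skipped = [], []
    for s in sites:
        try:
            kmer = extract_kmer(s, sequences, k=k)
            category = classify_motif(kmer)
        except ValueError as exc:
            skipped.append((s, str(exc)))
            continue
        calls.append(
            MotifCall(
                site=s,
                kmer=kmer,
                category=category,
                mettl16_context=mettl16_context(s, sequences),
            )
        )
    return calls, skipped


def motif_composition(calls: list[MotifCall], top_n: int = 10) -> dict:
    """Category fractions, top-ranked 5-mers and the position frequency
    matrix (rows = positions, columns = A/C/G/U, each row summing to 1)."""
    if not calls:
        raise ValueError("motif composition of an empty call set is undefined")
    n = len(calls)
    cat_counts = Counter(c.category for c in calls)
    kmer_counts = Counter(c.kmer for c in calls)
    k = len(calls[0].kmer)
    alphabet = "ACGU"
    pfm = np.zeros((k, 4))
    for c in calls:
        for i, b in enumerate(c.kmer):
            if b in alphabet:
                pfm[i, alphabet.index(b)] += 1
    pfm /= pfm.sum(axis=1, keepdims=True)
    return {
        "n": n,
        "category_fractions": {cat: cat_counts.get(cat, 0) / n for cat in CATEGORIES},
        "top_kmers": [
            {"kmer": km, "fraction": cnt / n}
            for km, cnt in kmer_counts.most_common(top_n)
        ],
        "pfm": pfm,
        "pfm_alphabet": alphabet,
        "mettl16_fraction": sum(c.mettl16_context for c in calls) / n,
    }


def enumerate_central_a_5mers():
    """All 256 5-mers with central A (RNA alphabet) — the exhaustive support
    of the motif hierarchy — plus, for convenience, the full 1024 5-mer
    space when the central base is left free."""
    import itertools

    bases = "ACGU"
    return [
        "".join(p[:2]) + "A" + "".join(p[2:])
        for p in itertools.product(bases, repeat=4)
    ]
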