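"""Termination-signature extraction, clustering and classification.

Base methylations (m6A, m5C) terminate RT precisely at a single offset,
ribose methylations (Nm) terminate stepwise at two adjacent offsets, and
Watson-Crick-face methylations (m1A) terminate in treated *and* control
samples.  The per-site signature is the vector of differential arrest
signal (treated minus control arrest rate, percentage points) at offsets
-3..+2 around the modified nucleotide in transcript orientation;
agglomerative hierarchical clustering with Euclidean distance cut at two
clusters separates the precise from the stepwise shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .annotate import Site
from .calling import ARREST_OFFSET, arrest_rate, expected_arrest_position
from .io import PileupTrack

#: transcript-orientation offsets around the modified nucleotide (0)
OFFSETS = tuple(range(-3, 3))
#: offsets used for box-plot style summaries
SUMMARY_OFFSETS = tuple(range(-2, 3))


@dataclass
class SignatureProfile:
    site: Site
    signal: np.ndarray  # differential signal at OFFSETS, percentage points
    offsets: tuple[int, ...] = OFFSETS
    cluster: int | None = None
    class_call: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (len(self.offsets),):
            raise ValueError("signal length does not match offsets")
        if not np.isfinite(self.signal).all():
            raise ValueError("non-finite signal values")


def _rate_at(track: PileupTrack, pos: int) -> float:
    return arrest_rate(int(track.arrest[pos]), int(track.coverage[pos]))


def extract_profile(
    site: Site,
    treated: PileupTrack,
    control: PileupTrack,
    offsets: tuple[int, ...] = OFFSETS,
    min_coverage: int = 4,
    signal: str = "arrest_rate",
) -> SignatureProfile:
    """Differential termination signal around one site.

    ``signal='arrest_rate'`` (default) uses the per-offset arrest-rate
    difference treated - control; ``signal='coverage'`` uses the normalized
    coverage decrement instead (control minus treated coverage, percent of
    the window maximum) — both orderings of the published signal are
    supported because the exact normalization is a free choice.

    Offsets are taken in transcript orientation (minus-strand sites read the
    genomic axis right-to-left).  Raises ``ValueError`` if the window leaves
    the reference or coverage falls below ``min_coverage`` at any offset in
    either sample.
    """
    sign = 1 if site.strand == "+" else -1
    positions = [site.position + sign * o for o in offsets]
    n = len(treated)
    if min(positions) < 0 or max(positions) >= n:
        raise ValueError(f"window around {site.position} off reference end")
    for p in positions:
        if treated.coverage[p] < min_coverage or control.coverage[p] < min_coverage:
            raise ValueError(f"coverage below {min_coverage} at offset position {p}")
    if signal == "arrest_rate":
        vec = np.array([_rate_at(treated, p) - _rate_at(control, p) for p in positions])
    elif signal == "coverage":
        dec = np.array(
            [float(control.coverage[p] - treated.coverage[p]) for p in positions]
        )
        scale = float(
            max(control.coverage[p] for p in positions)
        )
        vec = 100.0 * dec / scale if scale > 0 else dec
    else:
        raise ValueError(f"unknown signal {signal!r}")
    return SignatureProfile(site=site, signal=vec, offsets=offsets)


def extract_profiles(
    sites,
    treated: dict,
    control: dict,
    **kwargs,
) -> tuple[list[SignatureProfile], list[tuple[Site, str]]]:
    """Batch extraction over track sets keyed (reference, strand); sites
    that cannot be profiled are returned with the reason instead of raised."""
    profiles, skipped = [], []
    for s in sites:
        key = (s.reference, s.strand if (s.reference, s.strand) in treated else "+")
        if key not in treated or key not in control:
            skipped.append((s, "no track"))
            continue
        try:
            profiles.append(extract_profile(s, treated[key], control[key], **kwargs))
        except ValueError as exc:
            skipped.append((s, str(exc)))
    return profiles, skipped


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1 or 2 per profile, input order
    medians: dict[int, np.ndarray]  # per-cluster median signal
    classes: dict[int, str]  # per-cluster class call
    linkage: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False


def cluster_profiles(
    profiles: list[SignatureProfile],
    method: str = "average",
) -> ClusterResult:
    """Agglomerative hierarchical clustering of signature vectors (Euclidean
    distance), dendrogram cut into exactly two clusters.

    Deterministic given input order; if all profiles are identical the cut
    degenerates to an (n-1, 1) split under SciPy's tie rule and the result
    is flagged ``degenerate``.
    """
    if len(profiles) < 2:
        raise ValueError("clustering requires at least 2 profiles")
    X = np.vstack([p.signal for p in profiles])
    Z = hierarchy.linkage(X, method=method, metric="euclidean")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    degenerate = len(np.unique(labels)) < 2 or float(pdist(X).max()) == 0.0
    if len(np.unique(labels)) < 2:
        # all-identical input: force the tie-rule split (n-1, singleton)
        labels = np.ones(len(profiles), dtype=int)
        labels[-1] = 2
    medians = {
        int(c): np.median(X[labels == c], axis=0) for c in np.unique(labels)
    }
    classes = classify_clusters(medians, offsets=profiles[0].offsets)
    for p, lab in zip(profiles, labels):
        p.cluster = int(lab)
        p.class_call = classes[int(lab)]
    return ClusterResult(
        labels=labels, medians=medians, classes=classes, linkage=Z, degenerate=degenerate
    )


def classify_clusters(
    medians: dict[int, np.ndarray],
    offsets: tuple[int, ...] = OFFSETS,
    secondary_ratio: float = 0.3,
) -> dict[int, str]:
    """Call each cluster 'precise', 'stepwise' or 'ambiguous' from its median
    signal alone (no per-site heuristics).

    precise: the signal is concentrated at a single offset (second-largest /
    largest median < ``secondary_ratio``).  stepwise: the two largest
    entries are adjacent offsets and both exceed ``secondary_ratio`` x the
    maximum.  Anything else — including a flat or non-positive median — is
    ambiguous.
    """
    out: dict[int, str] = {}
    for c, med in medians.items():
        med = np.asarray(med, dtype=float)
        order = np.argsort(med)[::-1]
        primary, secondary = med[order[0]], med[order[1]]
        if primary <= 0:
            out[c] = "ambiguous"
        elif secondary / primary < secondary_ratio:
            out[c] = "precise"
        elif abs(offsets[order[0]] - offsets[order[1]]) == 1:
            out[c] = "stepwise"
        else:
            out[c] = "ambiguous"
    return out


def control_termination_flag(
    site: Site,
    control: PileupTrack,
    threshold: float = 20.0,
    min_coverage: int = 4,
) -> bool:
    """True iff the *control* sample already terminates strongly at the
    site's expected arrest position (> ``threshold`` percent).

    An inspection utility for putative m1A sites — methylation on the
    Watson-Crick face blocks RT without any metabolic label, so such sites
    show high arrest in both samples and never pass differential calling.
    """
    a = expected_arrest_position(site.position, site.strand)
    if not 0 <= a < len(control):
        raise ValueError("expected arrest position off reference")
    if control.coverage[a] < min_coverage:
        raise ValueError(f"coverage below {min_coverage} at arrest position")
    return _rate_at(control, a) > threshold
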