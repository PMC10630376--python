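"""Methyltransferase attribution by intersecting call sets.

In vitro labeling with a purified MTase (e.g. METTL16) marks that enzyme's
reachable targets but also off-targets of the non-natural reaction
conditions; metabolic labeling marks sites actually written in cells.  A
site is attributed to the enzyme only if it is reproducible (present in
both replicates) in *both* experiments — the exact single-nucleotide
intersection.  In vitro sites absent from the metabolic set are labeled
putative off-targets.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import Site, SiteSet


@dataclass
class AttributionResult:
    invitro: SiteSet
    metabolic: SiteSet
    attributed: SiteSet
    off_target: SiteSet

    @property
    def summary(self) -> dict:
        n_iv, n_met, n_att = len(self.invitro), len(self.metabolic), len(self.attributed)
        return {
            "n_invitro": n_iv,
            "n_metabolic": n_met,
            "n_attributed": n_att,
            "fraction_of_invitro": n_att / n_iv if n_iv else 0.0,
            "fraction_of_metabolic": n_att / n_met if n_met else 0.0,
        }


def reproducible(rep_a: SiteSet, rep_b: SiteSet) -> SiteSet:
    """Sites present in both replicates (exact reference/position/strand)."""
    return rep_a.intersection(rep_b)


def _fuzzy_keys(sites: SiteSet, window: int) -> set[tuple[str, int, str]]:
    keys = set()
    for s in sites:
        for d in range(-window, window + 1):
            keys.add((s.reference, s.position + d, s.strand))
    return keys


def attribute(
    invitro_reproducible: SiteSet,
    metabolic_reproducible: SiteSet,
    window: int = 0,
) -> AttributionResult:
    """Intersect reproducible in vitro and metabolic call sets.

    Matching is exact by default; ``window`` > 0 enables a +/- nt fuzzy
    match for cross-dataset comparisons (attributed sites are then reported
    from the in vitro set).
    """
    if window == 0:
        attributed = invitro_reproducible.intersection(metabolic_reproducible)
    else:
        fuzzy = _fuzzy_keys(metabolic_reproducible, window)
        attributed = SiteSet(
            [s for s in invitro_reproducible if s.key in fuzzy]
        )
    off_keys = invitro_reproducible.keys() - attributed.keys()
    off_target = SiteSet([s for s in invitro_reproducible if s.key in off_keys])
    return AttributionResult(
        invitro=invitro_reproducible,
        metabolic=metabolic_reproducible,
        attributed=attributed,
        off_target=off_target,
    )
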