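"""Per-gene quantification and intergenic-read normalization.

Site counts are summed into gene totals over each gene's core region only
(the central 80% of the ORF); insertions in the outer 10% on each side are
ignored because they may not knock the gene out.  Samples are made
comparable by scaling each one so its intergenic read total matches the
sample with the fewest intergenic reads — intergenic insertions are assumed
selectively neutral, so their recovery measures sequencing depth rather
than fitness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .mapping import SampleProfile
from .reference import CoreRegion, GeneRecord

__all__ = [
    "NormalizationSet",
    "assign_sites_to_genes",
    "intergenic_total",
    "normalization_factors",
    "normalize_profiles",
    "gene_count_table",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclass
class NormalizationSet:
    """Per-sample intergenic totals and the derived scale factors.

    NF(s) = min_t intergenic_total(t) / intergenic_total(s); the minimal
    sample(s) get NF = 1.
    """

    intergenic_totals: dict[str, int]
    factors: dict[str, float]
    reference_sample: str


def _core_trees(
    genes: list[GeneRecord], cores: dict[str, CoreRegion]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        core = cores[g.gene_id]
        if core.is_empty:
            continue
        tree = trees.setdefault(g.replicon_id, IntervalTree())
        # half-open interval over 1-based positions
        tree[core.core_start : core.core_end + 1] = g.gene_id
    return trees


def assign_sites_to_genes(
    profile: SampleProfile,
    genes: list[GeneRecord],
    cores: dict[str, CoreRegion],
) -> dict[str, int]:
    """Sum site counts into per-gene raw totals over core regions.

    A site contributes to every gene whose core contains its position,
    regardless of either strand; all genes appear in the result, zero when
    no core site was hit.
    """
    trees = _core_trees(genes, cores)
    totals = {g.gene_id: 0 for g in genes}
    for site, count in profile.site_counts.items():
        tree = trees.get(site.replicon_id)
        if tree is None:
            continue
        for iv in tree.at(site.position):
            totals[iv.data] += count
    return totals


def intergenic_total(
    profile: SampleProfile, mask: dict[str, list[tuple[int, int]]]
) -> int:
    """Reads at sites whose position falls between annotated genes."""
    # sorted interval arrays per replicon for bisection
    bounds = {
        rep: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for rep, ivs in mask.items()
    }
    total = 0
    for site, count in profile.site_counts.items():
        if site.replicon_id not in bounds:
            continue
        starts, ends = bounds[site.replicon_id]
        if starts.size == 0:
            continue
        i = int(np.searchsorted(starts, site.position, side="right")) - 1
        if i >= 0 and site.position <= ends[i]:
            total += count
    return total


def normalization_factors(
    intergenic_totals: dict[str, int]
) -> NormalizationSet:
    """Scale factors normalizing every sample to the minimum intergenic total.

    Grouping spans all samples handed in (by default the whole run, both
    replicates and all conditions together).
    """
    if not intergenic_totals:
        raise ValueError("no samples to normalize")
    for sample, tot in intergenic_totals.items():
        if tot <= 0:
            raise ValueError(
                f"sample {sample!r} has no intergenic reads; "
                "normalization is undefined"
            )
    minimum = min(intergenic_totals.values())
    reference = min(
        s for s, t in intergenic_totals.items() if t == minimum
    )
    factors = {s: minimum / t for s, t in intergenic_totals.items()}
    return NormalizationSet(dict(intergenic_totals), factors, reference)


def normalize_profiles(
    profiles: dict[str, SampleProfile],
    mask: dict[str, list[tuple[int, int]]],
) -> NormalizationSet:
    """Compute intergenic totals and NFs for a set of profiles, storing the
    factor and intergenic total on each profile."""
    totals = {
        sid: intergenic_total(p, mask) for sid, p in profiles.items()
    }
    normset = normalization_factors(totals)
    for sid, p in profiles.items():
        p.intergenic_reads = totals[sid]
        p.normalization_factor = normset.factors[sid]
    return normset


def gene_count_table(
    profiles: dict[str, SampleProfile],
    genes: list[GeneRecord],
    cores: dict[str, CoreRegion],
    normset: NormalizationSet,
) -> pd.DataFrame:
    """Gene x sample table with raw and normalized core-region counts.

    Columns form a MultiIndex (sample_id, {'raw','norm'}); normalized values
    are kept as reals (raw x NF) — rounding happens only in printed reports.
    """
    data: dict[tuple[str, str], pd.Series] = {}
    for sid, profile in profiles.items():
        raw = assign_sites_to_genes(profile, genes, cores)
        raw_s = pd.Series(raw, dtype=float)
        data[(sid, "raw")] = raw_s
        data[(sid, "norm")] = raw_s * normset.factors[sid]
    table = pd.DataFrame(data)
    table.index.name = "gene_id"
    return table.sort_index()
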