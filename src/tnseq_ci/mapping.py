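"""Exact mapping of genomic tags to insertion sites.

Tags are placed against the TagIndex with zero mismatches.  A tag present
at exactly one genomic location yields an insertion site; tags occurring
more than once are counted as ambiguous and discarded (random assignment is
available only as an explicitly seeded sensitivity mode), and absent tags
are unmapped.

Site convention: the site coordinate is the genomic base abutting the
transposon junction.  A forward-strand k-mer starting at 1-based s gives
site (s, +); a reverse-strand k-mer occupying forward coordinates
[s, s+k-1] gives site (s+k-1, -).
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .read_prep import PrepAccounting
from .reference import Replicon, TagIndex

__all__ = [
    "InsertionSite",
    "SampleProfile",
    "map_tag",
    "site_of",
    "tally_sites",
    "write_igv_track",
    "is_ta_site",
]


@dataclass(frozen=True, order=True)
class InsertionSite:
    """A unique transposon junction keyed by (replicon, position, strand)."""

    replicon_id: str
    position: int  # 1-based; first genomic base adjacent to the transposon
    strand: str


@dataclass
class SampleProfile:
    """One sequenced sample: per-site raw counts plus run statistics."""

    sample_id: str
    condition: str  # input | nontreated | treated:<label>
    replicate: int
    site_counts: dict[InsertionSite, int] = field(default_factory=dict)
    accounting: PrepAccounting = field(default_factory=PrepAccounting)
    aligned_reads: int = 0
    ambiguous_reads: int = 0
    unmapped_reads: int = 0
    normalization_factor: float = 1.0
    intergenic_reads: int = 0

    @property
    def alignment_rate(self) -> float:
        """Percent of used reads that mapped uniquely."""
        used = self.accounting.reads_used
        return 100.0 * self.aligned_reads / used if used else 0.0

    @property
    def n_sites(self) -> int:
        return sum(1 for c in self.site_counts.values() if c > 0)


def map_tag(tag: str, index: TagIndex):
    """Place a tag exactly: returns ('unique', location), ('ambiguous', None)
    or ('unmapped', None).  Location is (replicon_id, 1-based k-mer start on
    the forward strand, strand)."""
    hits = index.lookup(tag)
    if not hits:
        return "unmapped", None
    if len(hits) > 1:
        return "ambiguous", None
    return "unique", hits[0]


def site_of(location: tuple[str, int, str], k: int) -> InsertionSite:
    """Insertion site for a unique tag placement (junction-base convention)."""
    replicon_id, start, strand = location
    if strand == "+":
        return InsertionSite(replicon_id, start, "+")
    return InsertionSite(replicon_id, start + k - 1, "-")


def tally_sites(
    tags: Counter,
    index: TagIndex,
    sample_id: str = "",
    condition: str = "",
    replicate: int = 1,
    accounting: PrepAccounting | None = None,
    ambig_mode: str = "discard",
    seed: int | None = None,
) -> SampleProfile:
    """Tally per-site read counts from a multiset of tags.

    ``used = aligned + ambiguous + unmapped`` holds whenever *accounting*
    comes from the same tag multiset.  ``ambig_mode='random'`` assigns each
    ambiguous tag's reads to one of its locations uniformly (sensitivity
    analysis only; requires a seed).
    """
    if ambig_mode not in ("discard", "random"):
        raise ValueError("ambig_mode must be 'discard' or 'random'")
    rng = random.Random(seed) if ambig_mode == "random" else None
    profile = SampleProfile(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        accounting=accounting or PrepAccounting(),
    )
    counts = profile.site_counts
    for tag, n in tags.items():
        hits = index.lookup(tag)
        if not hits:
            profile.unmapped_reads += n
        elif len(hits) == 1:
            site = site_of(hits[0], index.k)
            counts[site] = counts.get(site, 0) + n
            profile.aligned_reads += n
        else:
            if rng is not None:
                site = site_of(rng.choice(hits), index.k)
                counts[site] = counts.get(site, 0) + n
                profile.aligned_reads += n
            else:
                profile.ambiguous_reads += n
    return profile


def is_ta_site(site: InsertionSite, replicons: dict[str, Replicon]) -> bool:
    """Whether the junction base begins a TA dinucleotide on the site strand
    (the mariner/HIMAR1 insertion signature)."""
    seq = replicons[site.replicon_id].sequence
    p = site.position - 1
    if site.strand == "+":
        return seq[p : p + 2] == "TA"
    # minus strand reads right-to-left on the forward sequence
    return p >= 1 and seq[p - 1 : p + 1] == "TA"


def write_igv_track(profile: SampleProfile, path: str | Path) -> None:
    """Write a variableStep WIG track of insertion density (IGV-compatible).

    Counts at the same position on opposite strands are summed; positions
    are emitted in ascending order per replicon.
    """
    per_rep: dict[str, dict[int, int]] = {}
    for site, count in profile.site_counts.items():
        pos_counts = per_rep.setdefault(site.replicon_id, {})
        pos_counts[site.position] = pos_counts.get(site.position, 0) + count
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{profile.sample_id}"\n')
        for replicon_id in sorted(per_rep):
            fh.write(f"variableStep chrom={replicon_id}\n")
            for pos in sorted(per_rep[replicon_id]):
                fh.write(f"{pos} {per_rep[replicon_id][pos]}\n")
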