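"""End-to-end pipeline: FASTQ samples to classified gene tables.

The run follows the three stages of junction sequencing analysis —
prealignment (transposon detection and tag extraction), alignment (exact
unique tag placement) and postalignment processing (gene quantification,
intergenic normalization, competition indices, classification) — driven by
a single configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import quantify
from .ci import CIParams, analyze_treatment, write_reports
from .mapping import SampleProfile, tally_sites, write_igv_track
from .quantify import NormalizationSet, round_half_away
from .read_prep import ReadPrepParams, process_fastq
from .reference import (
    CoreRegion,
    GeneRecord,
    build_tag_index,
    core_region,
    intergenic_mask,
    read_annotation,
    read_fasta,
)

__all__ = [
    "SampleSpec",
    "RunConfig",
    "run_pipeline",
    "analyze_profiles",
    "table1_report",
]

logger = logging.getLogger("tnseq_ci")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    fastq: str
    condition: str  # input | nontreated | treated:<label>
    replicate: int


@dataclass
class RunConfig:
    """Validated run configuration.

    Every replicate must declare exactly one input and one nontreated
    sample, and the run must include at least one treated condition.
    """

    genome: str
    annotations: list[dict]  # [{path, format, replicon_id}, ...]
    samples: list[SampleSpec]
    out_dir: str = "tnseq_out"
    prep: ReadPrepParams = field(default_factory=ReadPrepParams)
    ci: CIParams = field(default_factory=CIParams)
    norm_group: str = "run"  # or "replicate"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.norm_group not in ("run", "replicate"):
            raise ValueError("norm_group must be 'run' or 'replicate'")
        replicates = sorted({s.replicate for s in self.samples})
        if not replicates:
            raise ValueError("no samples configured")
        treatments = self.treatments()
        if not treatments:
            raise ValueError("at least one treated condition is required")
        for rep in replicates:
            for role in ("input", "nontreated"):
                n = sum(
                    1 for s in self.samples
                    if s.replicate == rep and s.condition == role
                )
                if n != 1:
                    raise ValueError(
                        f"replicate {rep} must have exactly one {role} sample "
                        f"(found {n})"
                    )
            for t in treatments:
                n = sum(
                    1 for s in self.samples
                    if s.replicate == rep and s.condition == f"treated:{t}"
                )
                if n != 1:
                    raise ValueError(
                        f"replicate {rep} must have exactly one treated:{t} "
                        f"sample (found {n})"
                    )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    def treatments(self) -> list[str]:
        return sorted({
            s.condition.split(":", 1)[1]
            for s in self.samples
            if s.condition.startswith("treated:")
        })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(**s) for s in raw["samples"]]
        prep = ReadPrepParams(**raw.get("prep", {}))
        ci = CIParams(**raw.get("ci", {}))
        return cls(
            genome=raw["genome"],
            annotations=raw["annotations"],
            samples=samples,
            out_dir=raw.get("out_dir", "tnseq_out"),
            prep=prep,
            ci=ci,
            norm_group=raw.get("norm_group", "run"),
        )


def _load_reference(config: RunConfig):
    replicons = read_fasta(config.genome)
    lengths = {r.id: r.length for r in replicons}
    genes: list[GeneRecord] = []
    for ann in config.annotations:
        rep_id = ann["replicon_id"]
        genes.extend(
            read_annotation(
                ann["path"], ann["format"], rep_id, lengths.get(rep_id)
            )
        )
    cores = {g.gene_id: core_region(g) for g in genes}
    mask = intergenic_mask(replicons, genes)
    return replicons, genes, cores, mask


def run_pipeline(config: RunConfig) -> dict:
    """Execute prealignment, alignment and postalignment for a whole run.

    Writes per-sample WIG tracks and site tables, the sample statistics
    table, per-treatment CI tables and hit lists, and a YAML log of every
    parameter and statistic.  Returns the in-memory results bundle.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("loading reference from %s", config.genome)
    replicons, genes, cores, mask = _load_reference(config)
    index = build_tag_index(replicons, k=config.prep.tag_length)

    profiles: dict[str, SampleProfile] = {}
    for spec in config.samples:
        logger.info("prealignment: %s (%s)", spec.sample_id, spec.fastq)
        try:
            tags, acct = process_fastq(spec.fastq, config.prep)
        except Exception as exc:  # annotate the failing stage and sample
            raise RuntimeError(
                f"prealignment failed for sample {spec.sample_id}: {exc}"
            ) from exc
        profile = tally_sites(
            tags,
            index,
            sample_id=spec.sample_id,
            condition=spec.condition,
            replicate=spec.replicate,
            accounting=acct,
        )
        profiles[spec.sample_id] = profile
        write_igv_track(profile, out_dir / f"{spec.sample_id}.wig")
        _write_site_table(profile, out_dir / f"{spec.sample_id}_sites.tsv")

    if config.norm_group == "run":
        normset = quantify.normalize_profiles(profiles, mask)
        normsets = {None: normset}
    else:
        normsets = {}
        for rep in sorted({s.replicate for s in config.samples}):
            group = {
                sid: p for sid, p in profiles.items() if p.replicate == rep
            }
            normsets[rep] = quantify.normalize_profiles(group, mask)
        normset = None

    table = quantify.gene_count_table(
        profiles, genes, cores,
        _merged_normset(normsets, profiles),
    )
    table.to_csv(out_dir / "gene_counts.tsv", sep="\t", float_format="%.6g")

    stats = table1_report(profiles)
    stats.to_csv(out_dir / "sample_stats.tsv", sep="\t", index=False)

    results = {"profiles": profiles, "gene_counts": table, "stats": stats,
               "normsets": normsets, "ci": {}}
    gene_norm = _norm_by_condition(table, profiles)
    for treatment in config.treatments():
        ci_table = analyze_treatment(gene_norm, f"treated:{treatment}", config.ci)
        write_reports(ci_table, treatment, out_dir)
        results["ci"][treatment] = ci_table

    _write_log(config, profiles, results, out_dir / "run_log.yaml")
    return results


def analyze_profiles(
    replicons,
    genes,
    profiles: dict[str, SampleProfile],
    ci_params: CIParams | None = None,
) -> dict:
    """Postalignment analysis of already-tallied sample profiles.

    Runs quantification, intergenic normalization and per-treatment CI
    classification on in-memory profiles (e.g. from the simulator's count
    path or a previous alignment stage).  Returns the same bundle shape as
    run_pipeline, without writing files.
    """
    ci_params = ci_params or CIParams()
    cores = {g.gene_id: core_region(g) for g in genes}
    mask = intergenic_mask(replicons, genes)
    normset = quantify.normalize_profiles(profiles, mask)
    table = quantify.gene_count_table(profiles, genes, cores, normset)
    gene_norm = _norm_by_condition(table, profiles)
    treatments = sorted({
        p.condition.split(":", 1)[1]
        for p in profiles.values()
        if p.condition.startswith("treated:")
    })
    ci_tables = {
        t: analyze_treatment(gene_norm, f"treated:{t}", ci_params)
        for t in treatments
    }
    return {
        "profiles": profiles,
        "gene_counts": table,
        "stats": table1_report(profiles),
        "normsets": {None: normset},
        "ci": ci_tables,
    }


def _merged_normset(normsets, profiles) -> NormalizationSet:
    factors = {}
    totals = {}
    for ns in normsets.values():
        factors.update(ns.factors)
        totals.update(ns.intergenic_totals)
    reference = min((s for s, f in factors.items() if f == 1.0), default="")
    return NormalizationSet(totals, factors, reference)


def _norm_by_condition(
    table: pd.DataFrame, profiles: dict[str, SampleProfile]
) -> pd.DataFrame:
    """Re-key the normalized block by (condition, replicate)."""
    cols = {}
    for sid, profile in profiles.items():
        cols[(profile.condition, profile.replicate)] = table[(sid, "norm")]
    return pd.DataFrame(cols)


def _write_site_table(profile: SampleProfile, path: Path) -> None:
    rows = sorted(
        (s.replicon_id, s.position, s.strand, c)
        for s, c in profile.site_counts.items()
    )
    with open(path, "w") as fh:
        fh.write("replicon\tposition\tstrand\traw_count\n")
        for rep, pos, strand, count in rows:
            fh.write(f"{rep}\t{pos}\t{strand}\t{count}\n")


def table1_report(profiles: dict[str, SampleProfile]) -> pd.DataFrame:
    """Per-sample run statistics in the standard eight-column layout.

    Columns: total reads, % reads with no transposon (2 dp), reads too
    short, reads used, alignment rate % (2 dp), NF (3 dp), total normalized
    reads (= round(total x NF) at the printed NF precision) and reads per
    insertion site (integer).
    """
    rows = []
    for sid, p in profiles.items():
        acct = p.accounting
        nf = round(p.normalization_factor, 3)
        normalized_total = round_half_away(acct.total_reads * nf)
        n_sites = p.n_sites
        reads_per_site = round_half_away(normalized_total / n_sites) if n_sites else 0
        if acct.reads_used == 0:
            logger.warning("sample %s has zero used reads", sid)
        rows.append({
            "sample_id": sid,
            "replicate": p.replicate,
            "condition": p.condition,
            "total_reads": acct.total_reads,
            "pct_no_tn": round(acct.pct_no_tn, 2),
            "reads_too_short": acct.reads_too_short,
            "reads_used": acct.reads_used,
            "alignment_rate": round(p.alignment_rate, 2),
            "nf": nf,
            "normalized_reads": normalized_total,
            "reads_per_site": reads_per_site,
        })
    return pd.DataFrame(rows)


def _write_log(config, profiles, results, path: Path) -> None:
    log = {
        "parameters": {
            "prep": vars(config.prep).copy(),
            "ci": vars(config.ci).copy(),
            "norm_group": config.norm_group,
        },
        "samples": {},
        "filters": {},
    }
    for sid, p in profiles.items():
        log["samples"][sid] = {
            "condition": p.condition,
            "replicate": p.replicate,
            "total_reads": p.accounting.total_reads,
            "reads_no_tn": p.accounting.reads_no_tn,
            "reads_too_short": p.accounting.reads_too_short,
            "reads_used": p.accounting.reads_used,
            "aligned": p.aligned_reads,
            "ambiguous": p.ambiguous_reads,
            "unmapped": p.unmapped_reads,
            "alignment_rate": round(p.alignment_rate, 2),
            "intergenic_reads": p.intergenic_reads,
            "normalization_factor": p.normalization_factor,
            "n_sites": p.n_sites,
        }
    for treatment, table in results["ci"].items():
        log["filters"][treatment] = {
            "underrepresented": int(table["underrepresented"].sum()),
            "growth_impaired": int(table["growth_impaired"].sum()),
            "analyzable": int(table["analyzable"].sum()),
            "reduced": int((table["classification"] == "REDUCED_COMPETITIVENESS").sum()),
            "increased": int((table["classification"] == "INCREASED_COMPETITIVENESS").sum()),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
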