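"""Competition-index analysis and gene classification.

For each treatment, a gene's competition index (CI) in a biological
replicate is the ratio of its normalized treated read count to its
normalized untreated (nontreated outgrowth) count.  CI = 1 means the
insertion left competitiveness unchanged; a gene is called only when both
independent replicates agree at a twofold change:

* REDUCED_COMPETITIVENESS  — CI <= 0.5 in both replicates (the gene
  protects against the treatment);
* INCREASED_COMPETITIVENESS — CI >= 2 in both replicates (the gene
  sensitizes);
* NO_CHANGE otherwise.

Before CI computation two filters exclude genes whose CI would be
meaningless: genes underrepresented in the starting culture (normalized
input count below 100 in either replicate — essential, pseudoessential or
insertion-poor genes), and genes whose insertions already impair growth
without treatment (nontreated/input ratio below 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "REDUCED",
    "INCREASED",
    "NO_CHANGE",
    "NOT_ANALYZED",
    "CIParams",
    "flag_underrepresented",
    "flag_growth_impaired",
    "compute_ci",
    "classify",
    "analyze_treatment",
    "write_reports",
]

REDUCED = "REDUCED_COMPETITIVENESS"
INCREASED = "INCREASED_COMPETITIVENESS"
NO_CHANGE = "NO_CHANGE"
NOT_ANALYZED = "NOT_ANALYZED"


@dataclass(frozen=True)
class CIParams:
    """Thresholds for filtering and classification.

    under_threshold: minimum normalized input count; genes strictly below it
        in either replicate are excluded ('lt' comparator; 'le' also offered
        since usage varies).
    growth_cutoff/growth_mode: nontreated/input ratio below the cutoff in
        either (default) or both replicates excludes the gene.
    low/high: inclusive CI cutoffs for the two call directions.
    pseudocount: added to treated and untreated counts when > 0; by default
        a zero untreated count leaves the CI undefined instead.
    """

    under_threshold: float = 100.0
    under_comparator: str = "lt"
    growth_cutoff: float = 0.5
    growth_mode: str = "either"
    low: float = 0.5
    high: float = 2.0
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.under_comparator not in ("lt", "le"):
            raise ValueError("under_comparator must be 'lt' or 'le'")
        if self.growth_mode not in ("either", "both"):
            raise ValueError("growth_mode must be 'either' or 'both'")


def flag_underrepresented(
    input_rep1: float, input_rep2: float, params: CIParams = CIParams()
) -> bool:
    """True when the normalized input count falls below the threshold in
    either biological replicate."""
    t = params.under_threshold
    if params.under_comparator == "lt":
        return input_rep1 < t or input_rep2 < t
    return input_rep1 <= t or input_rep2 <= t


def flag_growth_impaired(
    ratio_rep1: float, ratio_rep2: float, params: CIParams = CIParams()
) -> bool:
    """True when insertions impair growth without treatment: the
    nontreated/input ratio is below the cutoff in either (or both,
    depending on mode) replicate."""
    below1 = ratio_rep1 < params.growth_cutoff
    below2 = ratio_rep2 < params.growth_cutoff
    return (below1 or below2) if params.growth_mode == "either" else (below1 and below2)


def compute_ci(
    treated_norm: float, untreated_norm: float, pseudocount: float = 0.0
) -> float:
    """CI = normalized treated / normalized untreated; NaN when undefined."""
    assert treated_norm >= 0 and untreated_norm >= 0, "counts must be nonnegative"
    t = treated_norm + pseudocount
    u = untreated_norm + pseudocount
    if u == 0:
        return math.nan
    return t / u


def classify(
    ci_rep1: float, ci_rep2: float, low: float = 0.5, high: float = 2.0
) -> str:
    """Two-replicate concordance call with inclusive cutoffs."""
    if math.isnan(ci_rep1) or math.isnan(ci_rep2):
        return NOT_ANALYZED
    if ci_rep1 <= low and ci_rep2 <= low:
        return REDUCED
    if ci_rep1 >= high and ci_rep2 >= high:
        return INCREASED
    return NO_CHANGE


def analyze_treatment(
    gene_norm: pd.DataFrame,
    treatment: str,
    params: CIParams = CIParams(),
) -> pd.DataFrame:
    """Full per-gene CI analysis for one treatment.

    *gene_norm* carries normalized counts with MultiIndex columns
    (condition, replicate) where condition is 'input', 'nontreated' or the
    treatment label, and replicate is 1 or 2.

    Returns a DataFrame indexed by gene_id with input/nontreated/treated
    counts per replicate, filter flags, CI per replicate and the
    classification.  Genes failing a filter (or with undefined CI) are
    NOT_ANALYZED.
    """
    for cond in ("input", "nontreated", treatment):
        for rep in (1, 2):
            if (cond, rep) not in gene_norm.columns:
                raise ValueError(f"missing sample ({cond!r}, replicate {rep})")

    out = pd.DataFrame(index=gene_norm.index.copy())
    for rep in (1, 2):
        out[f"input_r{rep}"] = gene_norm[("input", rep)]
        out[f"nontreated_r{rep}"] = gene_norm[("nontreated", rep)]
        out[f"treated_r{rep}"] = gene_norm[(treatment, rep)]

    under = [
        flag_underrepresented(r.input_r1, r.input_r2, params)
        for r in out.itertuples()
    ]
    out["underrepresented"] = under

    ratios = {}
    for rep in (1, 2):
        inp = out[f"input_r{rep}"]
        ratios[rep] = out[f"nontreated_r{rep}"].where(inp > 0) / inp.where(inp > 0)
        out[f"growth_ratio_r{rep}"] = ratios[rep]
    growth = []
    for r1, r2, u in zip(ratios[1], ratios[2], under):
        if u:
            growth.append(False)  # filter applies only to represented genes
        else:
            assert not math.isnan(r1) and not math.isnan(r2), (
                "input count zero for a gene that passed the representation filter"
            )
            growth.append(flag_growth_impaired(r1, r2, params))
    out["growth_impaired"] = growth
    out["analyzable"] = ~out["underrepresented"] & ~out["growth_impaired"]

    ci1, ci2, calls = [], [], []
    for r in out.itertuples():
        if not r.analyzable:
            ci1.append(math.nan)
            ci2.append(math.nan)
            calls.append(NOT_ANALYZED)
            continue
        c1 = compute_ci(r.treated_r1, r.nontreated_r1, params.pseudocount)
        c2 = compute_ci(r.treated_r2, r.nontreated_r2, params.pseudocount)
        ci1.append(c1)
        ci2.append(c2)
        calls.append(classify(c1, c2, params.low, params.high))
    out["ci_rep1"] = ci1
    out["ci_rep2"] = ci2
    out["classification"] = calls
    return out.sort_index()


def write_reports(
    table: pd.DataFrame, treatment: str, out_dir: str | Path
) -> dict[str, Path]:
    """Write the three per-treatment gene-level TSVs.

    excluded: filtered genes with the reason; ci_table: the full analysis;
    hits: called genes split by direction.  Output is sorted by gene_id so
    reruns are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = table.sort_index()

    excluded = table[table["classification"] == NOT_ANALYZED].copy()
    reasons = []
    for r in excluded.itertuples():
        if r.underrepresented:
            reasons.append("underrepresented_in_input")
        elif r.growth_impaired:
            reasons.append("growth_impaired_untreated")
        else:
            reasons.append("ci_undefined")
    excluded["exclusion_reason"] = reasons

    hits = table[table["classification"].isin([REDUCED, INCREASED])].copy()
    hits = hits.sort_index().sort_values("classification", kind="stable")

    paths = {
        "excluded": out_dir / f"{treatment}_excluded_genes.tsv",
        "ci_table": out_dir / f"{treatment}_ci_table.tsv",
        "hits": out_dir / f"{treatment}_hits.tsv",
    }
    excluded.to_csv(paths["excluded"], sep="\t", float_format="%.6g")
    table.to_csv(paths["ci_table"], sep="\t", float_format="%.6g")
    hits.to_csv(paths["hits"], sep="\t", float_format="%.6g")
    return paths
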