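"""Descriptive statistics, group comparisons, and the end-to-end pipeline.

The statistics mirror standard practice for skewed comorbidity-count data:
medians with quartiles, Mann-Whitney U for binary groupings, Kruskal-Wallis
H (with epsilon-squared effect size) plus Dunn's post-hoc z tests under Holm
adjustment for multi-group comparisons. :func:`run_pipeline` orchestrates
the full analysis: diagnosis CSV -> coding/exclusion -> per-cohort and
per-period rule mining -> Jaccard comparison -> co-occurrence networks ->
summary tables, all written to an output bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml
from statsmodels.stats.multitest import multipletests

from . import arm_core, conet, ehr_coding, temporal_compare
from .arm_core import MiningConfig, RuleSet
from .conet import EdgeSelectionPolicy
from .ehr_coding import ExclusionPolicy, PatientRecord
from .errors import ComorbnetError, PipelineError
from .temporal_compare import PeriodDef, default_periods

__all__ = [
    "DistributionSummary",
    "GroupComparisonResult",
    "PipelineConfig",
    "PipelineResult",
    "summarize_distribution",
    "mann_whitney_u",
    "kruskal_wallis_dunn",
    "run_pipeline",
]

logger = logging.getLogger("comorbnet")


@dataclass(frozen=True)
class DistributionSummary:
    """Median/quartile summary of per-patient comorbidity counts."""

    n: int
    median: float
    p25: float
    p75: float
    min: float
    max: float
    histogram: dict[int, int]


@dataclass(frozen=True)
class GroupComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    #: (group_a, group_b, z, p_raw, p_adjusted) per pair, Holm-adjusted.
    pairwise: tuple[tuple[str, str, float, float, float], ...] = ()


def summarize_distribution(counts) -> DistributionSummary:
    """Median and quartiles by linear interpolation, plus a count histogram."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ComorbnetError("cannot summarize an empty count list")
    p25, median, p75 = np.percentile(counts, [25, 50, 75])
    values, freqs = np.unique(counts.astype(int), return_counts=True)
    return DistributionSummary(
        n=int(counts.size),
        median=float(median),
        p25=float(p25),
        p75=float(p75),
        min=float(counts.min()),
        max=float(counts.max()),
        histogram={int(v): int(f) for v, f in zip(values, freqs)},
    )


def mann_whitney_u(group_a, group_b) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U with midrank ties, tie-corrected normal
    approximation and continuity correction; reports the smaller of U1/U2."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ComorbnetError("Mann-Whitney groups must both be non-empty")
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return GroupComparisonResult("mann_whitney_u", u, float(res.pvalue))


def kruskal_wallis_dunn(groups, labels=None, adjust: str = "holm") -> GroupComparisonResult:
    """Kruskal-Wallis H with tie correction, epsilon-squared effect size, and
    Dunn's pairwise post-hoc z tests under Holm step-down adjustment.

    H = [12/(N(N+1))] * sum R_i^2/n_i - 3(N+1), divided by 1 - sum(t^3-t)/(N^3-N);
    epsilon^2 = H/(N-1). Dunn's z for groups i, j uses the pooled midranks:
    z = (meanR_i - meanR_j) / sqrt(S * (1/n_i + 1/n_j)) with the tie-corrected
    variance term S = N(N+1)/12 - sum(t^3-t)/(12(N-1)).
    """
    if adjust != "holm":
        raise ComorbnetError(f"unsupported adjustment: {adjust!r}")
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2:
        raise ComorbnetError("Kruskal-Wallis needs at least two groups")
    if any(g.size == 0 for g in groups):
        raise ComorbnetError("Kruskal-Wallis groups must all be non-empty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]

    pooled = np.concatenate(groups)
    n_total = pooled.size
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = scipy.stats.kruskal(*groups)
    eps2 = float(h) / (n_total - 1)

    ranks = scipy.stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    offset = 0
    for size in sizes:
        mean_ranks.append(ranks[offset : offset + size].mean())
        offset += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    s_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = list(combinations(range(len(groups)), 2))
    zs, raw = [], []
    for i, j in pairs:
        se = np.sqrt(s_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(float(z))
        raw.append(float(2.0 * scipy.stats.norm.sf(abs(z))))
    if raw:
        adjusted = multipletests(raw, method="holm")[1]
    else:
        adjusted = []
    pairwise = tuple(
        (labels[i], labels[j], zs[k], raw[k], float(adjusted[k]))
        for k, (i, j) in enumerate(pairs)
    )
    return GroupComparisonResult(
        "kruskal_wallis", float(h), float(p), effect_size=eps2, pairwise=pairwise
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; loadable from YAML."""

    input_path: Path
    output_dir: Path
    exclusion: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    index_codes: frozenset[str] = frozenset()
    mining: MiningConfig = field(default_factory=MiningConfig)
    periods: list[PeriodDef] = field(default_factory=default_periods)
    overall_policy: EdgeSelectionPolicy = field(
        default_factory=lambda: EdgeSelectionPolicy(mode="node_budget")
    )
    period_policy: EdgeSelectionPolicy = field(
        default_factory=lambda: EdgeSelectionPolicy(mode="top_k_edges", k=20)
    )
    min_conditions: int = 2
    jaccard_top_k: int = 20
    transaction_level: str = "patient"
    stage_map_path: Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {
            "input_path": Path(raw["input_path"]),
            "output_dir": Path(raw["output_dir"]),
        }
        if "exclusion_chapters" in raw:
            kwargs["exclusion"] = ExclusionPolicy(frozenset(raw["exclusion_chapters"]))
        if "index_codes" in raw:
            kwargs["index_codes"] = frozenset(raw["index_codes"])
        if "mining" in raw:
            kwargs["mining"] = MiningConfig(**raw["mining"])
        if "periods" in raw:
            kwargs["periods"] = [
                PeriodDef(p["label"], int(p["year_min"]), int(p["year_max"]))
                for p in raw["periods"]
            ]
        for key in ("min_conditions", "jaccard_top_k", "transaction_level", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stage_map_path" in raw and raw["stage_map_path"]:
            kwargs["stage_map_path"] = Path(raw["stage_map_path"])
        if "overall_policy" in raw:
            kwargs["overall_policy"] = EdgeSelectionPolicy(**raw["overall_policy"])
        if "period_policy" in raw:
            kwargs["period_policy"] = EdgeSelectionPolicy(**raw["period_policy"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Handles to everything the run computed and wrote."""

    output_dir: Path
    records: list[PatientRecord]
    cohort_records: list[PatientRecord]
    distribution: DistributionSummary
    ruleset: RuleSet
    period_rules: dict[str, RuleSet]
    comparisons: pd.DataFrame
    overall_network: conet.ComorbidityNetwork
    period_networks: dict[str, conet.ComorbidityNetwork]
    counts: dict[str, int]
    files: list[Path]


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the output bundle.

    Stages (each rejection is labeled with its stage): read the diagnosis
    CSV; consolidate/filter patients; restrict to the comorbidity cohort
    (>= ``min_conditions`` retained categories); mine frequent itemsets and
    rules overall and per period; compare period rule patterns by Jaccard;
    build the overall (node-budget) and per-period (top-20-edge) networks;
    summarize comorbidity counts and subgroup comparisons. All outputs are
    deterministic given (input, config).
    """
    logging.basicConfig(level=config.log_level)

    cfg_input = Path(config.input_path)
    if not cfg_input.exists():
        raise PipelineError("read", f"input file not found: {cfg_input}")
    try:
        rows = pd.read_csv(cfg_input)
    except Exception as exc:
        raise PipelineError("read", f"cannot parse {cfg_input}: {exc}") from exc
    if rows.empty:
        raise PipelineError("read", f"input file {cfg_input} has no rows")

    stage_map = ehr_coding.load_stage_map(config.stage_map_path)
    try:
        records = ehr_coding.ingest_rows(
            rows, config.exclusion, stage_map, config.index_codes
        )
    except ComorbnetError as exc:
        raise PipelineError("ingest", str(exc)) from exc
    if not records:
        raise PipelineError("ingest", "no patients retained after exclusion filtering")

    cohort = [r for r in records if r.n_comorbidities >= config.min_conditions]
    if not cohort:
        raise PipelineError(
            "cohort", f"no patients with >= {config.min_conditions} retained categories"
        )
    counts = {
        "input_rows": int(len(rows)),
        "patients_ingested": int(rows["patient_id"].nunique()),
        "patients_after_exclusion": len(records),
        "comorbidity_cohort": len(cohort),
    }
    logger.info("filter steps: %s", counts)

    # --- mining (overall) ---
    transactions = ehr_coding.build_transactions(cohort, config.transaction_level)
    frequent = arm_core.mine_frequent(transactions, config.mining)
    ruleset = arm_core.generate_rules(frequent, config.mining, transactions.n)

    # --- per-period mining & comparison ---
    by_period = temporal_compare.split_by_period(cohort, config.periods)
    period_rules: dict[str, RuleSet] = {}
    period_transactions: dict[str, ehr_coding.TransactionSet] = {}
    for label, recs in by_period.items():
        if not recs:
            logger.warning("period %s has no patients; skipped", label)
            continue
        ts = ehr_coding.build_transactions(recs, config.transaction_level)
        period_transactions[label] = ts
        period_rules[label] = arm_core.mine_rules(ts, config.mining)

    comparison_rows = []
    for la, lb in combinations(sorted(period_rules), 2):
        try:
            cmp_res = temporal_compare.jaccard_topk(
                period_rules[la], period_rules[lb], config.jaccard_top_k
            )
        except ComorbnetError:
            continue
        comparison_rows.append(
            {
                "period_a": la,
                "period_b": lb,
                "k": config.jaccard_top_k,
                "jaccard": cmp_res.jaccard,
                "n_shared": len(cmp_res.shared_patterns),
            }
        )
    comparisons = pd.DataFrame(
        comparison_rows, columns=["period_a", "period_b", "k", "jaccard", "n_shared"]
    )

    # --- networks ---
    overall_edges = conet.cooccurrence_edges(transactions)
    overall_network = conet.build_network(overall_edges, config.overall_policy)
    period_networks: dict[str, conet.ComorbidityNetwork] = {}
    for label, ts in period_transactions.items():
        edges = conet.cooccurrence_edges(ts)
        if edges:
            period_networks[label] = conet.build_network(edges, config.period_policy)

    # --- statistics ---
    cohort_counts = [r.n_comorbidities for r in cohort]
    distribution = summarize_distribution(cohort_counts)
    ks_stat, ks_p = scipy.stats.kstest(
        (np.asarray(cohort_counts) - np.mean(cohort_counts)) / (np.std(cohort_counts) or 1.0),
        "norm",
    )
    logger.info("normality check (KS vs standard normal): D=%.4f p=%.3g", ks_stat, ks_p)

    def values(pred):
        return [r.n_comorbidities for r in cohort if pred(r)]

    comparisons_rows = []
    for name, split in (
        ("gender", lambda r: r.gender == "male"),
        ("residence", lambda r: r.residence == "rural"),
    ):
        grp_a, grp_b = values(split), values(lambda r, s=split: not s(r))
        if grp_a and grp_b:
            res = mann_whitney_u(grp_a, grp_b)
            comparisons_rows.append(
                {
                    "comparison": name,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "effect_size": "",
                }
            )
    period_groups = {
        label: [r.n_comorbidities for r in recs] for label, recs in by_period.items() if recs
    }
    period_kw: GroupComparisonResult | None = None
    if len(period_groups) >= 2:
        period_kw = kruskal_wallis_dunn(
            list(period_groups.values()), labels=list(period_groups)
        )
        comparisons_rows.append(
            {
                "comparison": "admission_period",
                "test": period_kw.test_name,
                "statistic": period_kw.statistic,
                "p_value": period_kw.p_value,
                "effect_size": period_kw.effect_size,
            }
        )
    subgroup_table = pd.DataFrame(
        comparisons_rows, columns=["comparison", "test", "statistic", "p_value", "effect_size"]
    )

    stage_tally = pd.Series([r.who_stage for r in cohort]).value_counts().sort_index()
    stage_table = pd.DataFrame(
        {"who_stage": stage_tally.index, "n_patients": stage_tally.values}
    )

    # --- write bundle (only after every stage succeeded) ---
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def record(path: Path) -> Path:
        files.append(path)
        return path

    _float_csv(
        arm_core.itemsets_to_frame(frequent, min_len=2),
        record(out / "frequent_itemsets.csv"),
    )
    _float_csv(arm_core.rules_to_frame(ruleset.rules), record(out / "rules.csv"))
    for label, rs in period_rules.items():
        _float_csv(
            arm_core.rules_to_frame(rs.rules), record(out / f"rules_{label}.csv")
        )
    _float_csv(comparisons, record(out / "jaccard.csv"))

    conet.export_network(overall_network, record(out / "network_overall.gexf"), "gexf")
    conet.export_network(
        overall_network, record(out / "network_overall_edges.csv"), "edge_csv"
    )
    summary_rows = [{"period": "overall", **asdict(overall_network.summary)}]
    _float_csv(
        overall_network.nodes, record(out / "network_overall_nodes.csv")
    )
    for label, net in period_networks.items():
        conet.export_network(net, record(out / f"network_{label}.gexf"), "gexf")
        conet.export_network(
            net, record(out / f"network_{label}_edges.csv"), "edge_csv"
        )
        _float_csv(net.nodes, record(out / f"network_{label}_nodes.csv"))
        summary_rows.append({"period": label, **asdict(net.summary)})
    _float_csv(pd.DataFrame(summary_rows), record(out / "network_summaries.csv"))

    dist_frame = pd.DataFrame(
        [
            {
                "n": distribution.n,
                "median": distribution.median,
                "p25": distribution.p25,
                "p75": distribution.p75,
                "min": distribution.min,
                "max": distribution.max,
            }
        ]
    )
    _float_csv(dist_frame, record(out / "comorbidity_distribution.csv"))
    _float_csv(
        pd.DataFrame(
            sorted(distribution.histogram.items()), columns=["n_comorbidities", "n_patients"]
        ),
        record(out / "comorbidity_histogram.csv"),
    )
    _float_csv(subgroup_table, record(out / "subgroup_comparisons.csv"))
    if period_kw is not None:
        _float_csv(
            pd.DataFrame(
                list(period_kw.pairwise),
                columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"],
            ),
            record(out / "period_dunn_posthoc.csv"),
        )
    _float_csv(stage_table, record(out / "who_stage_tally.csv"))

    run_log = {
        "seed": config.seed,
        "quartile_convention": "linear interpolation (inclusive)",
        "counts": counts,
        "normality_ks": {"statistic": float(ks_stat), "p_value": float(ks_p)},
        "config": {
            "input_path": str(cfg_input),
            "exclusion_chapters": sorted(config.exclusion.excluded_chapters),
            "index_codes": sorted(config.index_codes),
            "mining": asdict(config.mining),
            "periods": [asdict(p) for p in config.periods],
            "min_conditions": config.min_conditions,
            "jaccard_top_k": config.jaccard_top_k,
            "transaction_level": config.transaction_level,
        },
    }
    with open(record(out / "run_log.json"), "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)

    return PipelineResult(
        output_dir=out,
        records=records,
        cohort_records=cohort,
        distribution=distribution,
        ruleset=ruleset,
        period_rules=period_rules,
        comparisons=comparisons,
        overall_network=overall_network,
        period_networks=period_networks,
        counts=counts,
        files=files,
    )
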