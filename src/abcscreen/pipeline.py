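"""End-to-end analysis: plates in, disruption scores and calls out.

``analyze_plate`` runs one experiment (one chemical and its controls)
through normalization, spline fitting and ABC scoring; ``analyze_study``
maps it over a set of plates and adds concentration-trend tests;
``roc_analysis``/``classify_study`` turn per-chemical scores and
reference labels into an operating threshold and binary calls; and
``table2_benchmark`` reruns the classification stage on the packaged
ECVAM validation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disruption import AbcResult, ChemicalSummary, abc, endpoint_score, sum_abc
from .io import (
    ROLE_CHEMICAL_BFGF,
    VEHICLE,
    PlateTimeSeries,
    RunConfig,
    StudyDesign,
    read_validation_table,
)
from .normalize import NormalizationMeta, normalize_plate
from .splines import SplineCurve, fit_spline
from .stats import (
    ChemicalCall,
    RocResult,
    TrendResult,
    classify_chemical,
    evaluate_threshold,
    jonckheere_terpstra,
    optimal_threshold,
    roc_auc,
)

__all__ = [
    "PlateAnalysis",
    "StudyResult",
    "analyze_plate",
    "analyze_study",
    "roc_analysis",
    "classify_study",
    "table2_benchmark",
    "null_trend_rejection_rate",
]


@dataclass
class PlateAnalysis:
    """Result of one experiment's ABC analysis."""

    chemical: str
    summary: ChemicalSummary
    per_concentration: list[AbcResult]
    replicate_abc: pd.DataFrame  # chemical, concentration, replicate, abc
    control_curve: SplineCurve
    chemical_curves: dict[float, SplineCurve]
    meta: NormalizationMeta


@dataclass
class StudyResult:
    summaries: dict[str, ChemicalSummary]
    trends: dict[str, TrendResult]
    analyses: dict[str, PlateAnalysis] = field(repr=False, default_factory=dict)

    @property
    def score_table(self) -> pd.DataFrame:
        rows = [
            {
                "chemical": s.chemical,
                "sum_abc": s.sum_abc,
                "endpoint_score_24h": s.endpoint_score_24h,
                "direction_profile": s.direction_profile,
                "jt_p_value": self.trends[name].p_value if name in self.trends else np.nan,
            }
            for name, s in sorted(self.summaries.items())
        ]
        return pd.DataFrame(rows)


def _fit_control(fc: pd.DataFrame, config: RunConfig, grid: np.ndarray) -> SplineCurve:
    if config.control_curve == "zero":
        return SplineCurve(grid=grid, values=np.zeros_like(grid), effective_df=0.0)
    veh = fc[fc["chemical"] == VEHICLE]
    return fit_spline(veh["time_h"].to_numpy(), veh["log_fc"].to_numpy(), config.spline_df, grid)


def analyze_plate(plate: PlateTimeSeries, config: RunConfig | None = None) -> PlateAnalysis:
    """ABC analysis of a single-chemical experiment.

    The control curve is fitted to the pooled vehicle-replicate log fold
    changes (each vehicle well against the vehicle mean); each
    concentration's chemical curve pools its replicates.  Per-replicate
    ABC values (replicate curve vs. the pooled control) feed the trend
    test and the replicate sum-of-ABC distribution used for Hedges' g.
    """
    config = config or RunConfig()
    chems = plate.chemicals
    if len(chems) != 1:
        raise ValueError(f"analyze_plate expects one chemical per plate, found {chems}")
    chem = chems[0]

    fc, meta = normalize_plate(plate, config)
    grid = config.eval_grid
    control = _fit_control(fc, config, grid)

    chem_fc = fc[fc["role"] == ROLE_CHEMICAL_BFGF]
    per_conc: list[AbcResult] = []
    curves: dict[float, SplineCurve] = {}
    endpoint_sum = 0.0
    rep_rows: list[dict] = []
    for conc, sub in sorted(chem_fc.groupby("concentration_ug_ml"), key=lambda kv: kv[0]):
        curve = fit_spline(sub["time_h"].to_numpy(), sub["log_fc"].to_numpy(), config.spline_df, grid)
        curves[float(conc)] = curve
        per_conc.append(abc(control, curve, name=chem, concentration=float(conc)))
        endpoint_sum += endpoint_score(control, curve, t=config.window[1])
        for rep, rsub in sub.groupby("replicate"):
            rep_curve = fit_spline(
                rsub["time_h"].to_numpy(), rsub["log_fc"].to_numpy(), config.spline_df, grid
            )
            rep_rows.append(
                {
                    "chemical": chem,
                    "concentration_ug_ml": float(conc),
                    "replicate": int(rep),
                    "abc": abc(control, rep_curve).abc,
                }
            )
    rep_df = pd.DataFrame(rep_rows)
    rep_sums = tuple(rep_df.groupby("replicate")["abc"].sum().sort_index().to_list())
    summary = sum_abc(per_conc, replicate_sums=rep_sums, endpoint_score_24h=endpoint_sum)
    return PlateAnalysis(
        chemical=chem,
        summary=summary,
        per_concentration=per_conc,
        replicate_abc=rep_df,
        control_curve=control,
        chemical_curves=curves,
        meta=meta,
    )


def analyze_study(plates: dict[str, PlateTimeSeries], config: RunConfig | None = None) -> StudyResult:
    """Run the per-plate analysis for every chemical and test trends."""
    config = config or RunConfig()
    result = StudyResult(summaries={}, trends={}, analyses={})
    for chem, plate in sorted(plates.items()):
        pa = analyze_plate(plate, config)
        result.analyses[chem] = pa
        result.summaries[chem] = pa.summary
        groups = [
            g["abc"].to_numpy()
            for _, g in sorted(
                pa.replicate_abc.groupby("concentration_ug_ml"), key=lambda kv: kv[0]
            )
        ]
        if len(groups) >= 2:
            result.trends[chem] = jonckheere_terpstra(groups, alpha=config.jt_alpha, chemical=chem)
    return result


def roc_analysis(scores, labels) -> RocResult:
    """ROC with pair-concordance AUC and the closest-to-corner operating point."""
    return optimal_threshold(roc_auc(scores, labels))


def classify_study(
    summaries: dict[str, ChemicalSummary],
    labels: dict[str, str],
    config: RunConfig | None = None,
) -> tuple[RocResult, dict[str, ChemicalCall]]:
    """Derive the operating threshold from labelled chemicals and call all of them."""
    config = config or RunConfig()
    names = sorted(set(summaries) & set(labels))
    roc = roc_analysis(
        [summaries[n].sum_abc for n in names], [labels[n] for n in names]
    )
    calls = {
        n: classify_chemical(s, roc.optimal_threshold, config.hedges_g_min_effect)
        for n, s in summaries.items()
    }
    return roc, calls


def null_trend_rejection_rate(
    n_chemicals: int = 1000,
    config: RunConfig | None = None,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> float:
    """Type-I error of the concentration-trend test under the synthetic null.

    Simulates ``n_chemicals`` independent experiments with zero
    disruption (``delta_max = 0``), runs each through the full pipeline
    and reports the fraction whose Jonckheere-Terpstra test rejects at
    the configured alpha.  Under a calibrated test this fraction sits
    near alpha.
    """
    from .simulate import SignalModelParams, generate_timecourse

    config = config or RunConfig()
    params = SignalModelParams(delta_max=0.0, noise_sd=noise_sd)
    design = StudyDesign(chemical="NULLCHEM", max_concentration=100.0)
    seeds = np.random.SeedSequence(seed).spawn(n_chemicals)
    rejections = 0
    for child in seeds:
        plate = generate_timecourse(
            params, design, config, seed=int(child.generate_state(1)[0] % 2**31)
        )
        pa = analyze_plate(plate, config)
        groups = [
            g["abc"].to_numpy()
            for _, g in sorted(pa.replicate_abc.groupby("concentration_ug_ml"), key=lambda kv: kv[0])
        ]
        if jonckheere_terpstra(groups, alpha=config.jt_alpha).significant:
            rejections += 1
    return rejections / n_chemicals


def table2_benchmark(path=None) -> dict:
    """Classification stage rerun on the packaged ECVAM validation scores.

    Computes the dynamic-assay AUC for three label sets -- all 18
    chemicals (animal P vs. N), the 7 limb-malformation toxicants vs.
    the 6 negatives, and the replotted limb set with 6-AN and BrdU moved
    into the positives -- plus the closest-to-corner threshold of the
    all-chemical ROC and the resulting in-vitro calls.
    """
    table = read_validation_table(path)
    scores = table["sum_abc"].to_numpy()
    labels = table["animal_label"].to_numpy()
    abbrev = table["abbreviation"].to_numpy()
    limb = table["limb_flag"].to_numpy()

    roc_all = roc_analysis(scores, labels)

    keep_limb = limb | (labels == "N")
    roc_limb = roc_analysis(scores[keep_limb], limb[keep_limb])

    extra = limb | np.isin(abbrev, ["6-AN", "BrdU"])
    keep_re = extra | (labels == "N")
    roc_replot = roc_analysis(scores[keep_re], extra[keep_re])

    thr = roc_all.optimal_threshold
    sens, spec, acc = evaluate_threshold(scores, labels, thr)
    calls = {a: ("P" if s >= thr else "N") for a, s in zip(abbrev, scores)}
    return {
        "table": table,
        "roc_all": roc_all,
        "roc_limb": roc_limb,
        "roc_limb_replotted": roc_replot,
        "threshold": thr,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "calls": calls,
    }
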