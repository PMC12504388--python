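"""Simulation-study harness and distribution-overlap metrics.

Two Monte Carlo studies probe the conjoint-check statistic:

* Study 1 crosses sample size (250/1000), test length (20/50), difficulty
  spread (variance 0.25 "narrow" / 1.44 "wide"), and data-generating
  discrimination (Rasch unit / U(0.8, 1.2) narrow / U(0.5, 1.7) wide),
  theta ~ N(0, 1) throughout, and summarizes the weighted violation
  proportion per condition plus its distributional separation from the
  matched Rasch condition (pooled-SD standardized mean difference and the
  overlapping index eta).
* Study 2 wraps the bootstrap-null procedure around each replicate and
  reports percentile summaries and rejection proportions at the 90/95/99
  cutoffs.

Scale knobs (replications, 3-matrices per dataset, bootstrap replicates,
chain length) are explicit arguments so the full published design and a
desk-scale replica share one code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from conjointcheck.bcc import MCMCConfig, run_bcc
from conjointcheck.datagen import draw_item_params, draw_person_params, simulate_responses
from conjointcheck.nullboot import CUTOFFS, bootstrap_null, compare_to_null

__all__ = [
    "DIFF_SPREADS",
    "DISC_SPREADS",
    "StudyCondition",
    "ConditionSummary",
    "OverlapStats",
    "StudyOneResult",
    "StudyTwoResult",
    "smd_pooled",
    "overlap_eta",
    "default_study1_conditions",
    "run_study1",
    "run_study2",
]

logger = logging.getLogger(__name__)

# difficulty-spread names -> variance of the N(0, sigma^2) difficulty distribution
DIFF_SPREADS = {"narrow": 0.25, "wide": 1.44}
# discrimination-spread names -> generator spec
DISC_SPREADS = {"rasch": "rasch", "narrow": "uniform(0.8,1.2)", "wide": "uniform(0.5,1.7)"}


@dataclass(frozen=True)
class StudyCondition:
    """One cell of the simulation design."""

    n: int
    j: int
    diff: str  # "narrow" or "wide"
    disc: str  # "rasch", "narrow", or "wide"
    reps: int = 100

    def __post_init__(self) -> None:
        if self.n <= 0 or self.j <= 0 or self.reps <= 0:
            raise ValueError("n, j, and reps must be positive")
        if self.diff not in DIFF_SPREADS:
            raise ValueError(f"diff must be one of {sorted(DIFF_SPREADS)}")
        if self.disc not in DISC_SPREADS:
            raise ValueError(f"disc must be one of {sorted(DISC_SPREADS)}")

    @property
    def label(self) -> str:
        return f"n{self.n}_j{self.j}_{self.diff}_{self.disc}"


@dataclass(frozen=True)
class ConditionSummary:
    mean: float
    sd: float
    reps_completed: int


@dataclass(frozen=True)
class OverlapStats:
    smd: float
    eta: float


@dataclass(frozen=True)
class StudyOneResult:
    summaries: pd.DataFrame  # per-condition mean/SD of weighted props
    overlaps: pd.DataFrame  # non-Rasch vs matched Rasch contrasts
    values: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class StudyTwoResult:
    props: pd.DataFrame  # distribution of weighted violation proportions
    percentiles: pd.DataFrame  # percentile summaries + rejection proportions
    raw: pd.DataFrame = None  # type: ignore[assignment]  # per-replication records


def smd_pooled(x, y) -> float:
    """Standardized mean difference (mean(x) - mean(y)) / pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var <= 0:
        raise ValueError("pooled standard deviation is zero")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def overlap_eta(x, y, grid_size: int = 1024) -> float:
    """Overlapping index: integral of min of the two kernel density estimates.

    Gaussian kernels with the normal-reference bandwidth 1.06 s n^(-1/5);
    the grid spans the pooled range padded by 3 bandwidths. Ranges from 0
    (disjoint distributions) to 1 (identical).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("each sample needs at least 5 values")
    hx, hy = _nrd_bandwidth(x), _nrd_bandwidth(y)
    pad = 3.0 * max(hx, hy)
    lo = min(x.min(), y.min()) - pad
    hi = max(x.max(), y.max()) + pad
    grid = np.linspace(lo, hi, grid_size)
    fx = _gauss_kde(x, hx, grid)
    fy = _gauss_kde(y, hy, grid)
    eta = float(np.trapezoid(np.minimum(fx, fy), grid))
    return float(np.clip(eta, 0.0, 1.0))


def _nrd_bandwidth(x: np.ndarray) -> float:
    s = x.std(ddof=1)
    if s <= 0:
        raise ValueError("degenerate zero-variance sample")
    return 1.06 * s * x.size ** (-0.2)


def _gauss_kde(x: np.ndarray, h: float, grid: np.ndarray) -> np.ndarray:
    z = (grid[:, None] - x[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2.0 * np.pi))


def default_study1_conditions(reps: int = 100) -> list[StudyCondition]:
    """The fully crossed 24-cell design."""
    return [
        StudyCondition(n=n, j=j, diff=d, disc=a, reps=reps)
        for n in (250, 1000)
        for j in (20, 50)
        for d in ("narrow", "wide")
        for a in ("rasch", "narrow", "wide")
    ]


def _condition_props(
    cond: StudyCondition,
    m: int,
    cfg: MCMCConfig,
    ss: np.random.SeedSequence,
) -> np.ndarray:
    """Weighted violation proportions across a condition's replications."""
    out = []
    for rep, child in enumerate(ss.spawn(cond.reps)):
        s_person, s_item, s_resp, s_bcc = child.spawn(4)
        logger.info("condition %s rep %d seed %s", cond.label, rep, child.spawn_key)
        try:
            persons = draw_person_params(cond.n, 0.0, 1.0, seed=s_person)
            items = draw_item_params(
                cond.j, 0.0, DIFF_SPREADS[cond.diff], disc=DISC_SPREADS[cond.disc],
                seed=s_item, scale="var",
            )
            data = simulate_responses(persons, items, seed=s_resp)
            rep_cfg = MCMCConfig(
                burn_in=cfg.burn_in,
                kept_draws=cfg.kept_draws,
                credible_level=cfg.credible_level,
                seed=int(s_bcc.generate_state(1)[0] % (2**31)),
            )
            out.append(run_bcc(data, m=m, cfg=rep_cfg).weighted_prop)
        except (ValueError, RuntimeError) as exc:
            logger.warning("condition %s rep %d failed: %s", cond.label, rep, exc)
    return np.asarray(out)


def run_study1(
    conditions: list[StudyCondition] | None = None,
    m: int = 5000,
    cfg: MCMCConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> StudyOneResult:
    """Run the sensitivity study and summarize each condition.

    For each condition: simulate `reps` datasets, run the conjoint check on
    each, and record the weighted violation proportion. Each non-Rasch
    condition is contrasted against the Rasch condition with the same
    (n, j, difficulty spread) via SMD (non-Rasch minus Rasch) and eta.
    Monte-Carlo standard errors of the means accompany the summaries.
    """
    conditions = conditions if conditions is not None else default_study1_conditions()
    cfg = cfg or MCMCConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    values: dict[str, np.ndarray] = {}
    rows = []
    for cond, child in zip(conditions, ss.spawn(len(conditions))):
        vals = _condition_props(cond, m, cfg, child)
        values[cond.label] = vals
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                "n": cond.n,
                "j": cond.j,
                "diff": cond.diff,
                "disc": cond.disc,
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": sd,
                "mc_se": sd / np.sqrt(vals.size) if vals.size else np.nan,
                "reps_completed": int(vals.size),
            }
        )
    summaries = pd.DataFrame(rows)
    contrasts = []
    by_key = {(c.n, c.j, c.diff, c.disc): c.label for c in conditions}
    for cond in conditions:
        if cond.disc == "rasch":
            continue
        rasch_label = by_key.get((cond.n, cond.j, cond.diff, "rasch"))
        if rasch_label is None:
            continue
        x, y = values[cond.label], values[rasch_label]
        if x.size < 2 or y.size < 2:
            continue
        contrasts.append(
            {
                "n": cond.n,
                "j": cond.j,
                "diff": cond.diff,
                "disc": cond.disc,
                "smd": smd_pooled(x, y),
                "eta": overlap_eta(x, y) if min(x.size, y.size) >= 5 else np.nan,
            }
        )
    return StudyOneResult(summaries=summaries, overlaps=pd.DataFrame(contrasts), values=values)


def run_study2(
    n: int = 1000,
    j: int = 50,
    diff: str = "wide",
    disc: str = "wide",
    reps: int = 100,
    b_reps: int = 100,
    m: int = 5000,
    cfg: MCMCConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> StudyTwoResult:
    """Evaluate the bootstrap-null procedure at one data-generating design.

    Per replication: simulate a dataset, run the conjoint check, build the
    dataset's bootstrap null, and locate the statistic's percentile.
    Returns the distribution of weighted violation proportions and the
    percentile/rejection summary.
    """
    cfg = cfg or MCMCConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    records = []
    for rep, child in enumerate(ss.spawn(reps)):
        s_person, s_item, s_resp, s_bcc, s_null = child.spawn(5)
        logger.info("study-2 rep %d seed %s", rep, child.spawn_key)
        try:
            persons = draw_person_params(n, 0.0, 1.0, seed=s_person)
            items = draw_item_params(
                j, 0.0, DIFF_SPREADS[diff], disc=DISC_SPREADS[disc], seed=s_item, scale="var"
            )
            data = simulate_responses(persons, items, seed=s_resp)
            rep_cfg = MCMCConfig(
                burn_in=cfg.burn_in,
                kept_draws=cfg.kept_draws,
                credible_level=cfg.credible_level,
                seed=int(s_bcc.generate_state(1)[0] % (2**31)),
            )
            stat = run_bcc(data, m=m, cfg=rep_cfg).weighted_prop
            null = bootstrap_null(data, b_reps=b_reps, m=m, cfg=cfg, seed=s_null)
            comp = compare_to_null(stat, null)
            records.append(
                {
                    "rep": rep,
                    "weighted_prop": stat,
                    "percentile": comp.percentile,
                    **{f"rejected_{c}": comp.rejected_at[c] for c in CUTOFFS},
                }
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("study-2 replication %d failed: %s", rep, exc)
    raw = pd.DataFrame(records)
    props = raw["weighted_prop"].to_numpy()
    pct = raw["percentile"].to_numpy()
    props_summary = pd.DataFrame(
        [
            {
                "n_replications": len(raw),
                "mean": props.mean(),
                "median": float(np.median(props)),
                "sd": props.std(ddof=1) if props.size > 1 else 0.0,
                "min": props.min(),
                "max": props.max(),
                "pct05": float(np.percentile(props, 5)),
                "pct95": float(np.percentile(props, 95)),
            }
        ]
    )
    pct_summary = pd.DataFrame(
        [
            {
                "n_replications": len(raw),
                "mean_percentile": pct.mean(),
                "median_percentile": float(np.median(pct)),
                "sd_percentile": pct.std(ddof=1) if pct.size > 1 else 0.0,
                "min_percentile": pct.min(),
                **{f"prop_rejected_{c}": float(raw[f"rejected_{c}"].mean()) for c in CUTOFFS},
            }
        ]
    )
    return StudyTwoResult(props=props_summary, percentiles=pct_summary, raw=raw)
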