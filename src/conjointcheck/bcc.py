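"""Bayesian conjoint checks of single and double cancellation.

The analysis object is the summary table: rows are groups of examinees
sharing a sum score, columns are items ordered by marginal proportion
correct, cells are the proportion of the score group answering the item
correctly. Under any data-generating process compatible with additive
conjoint measurement these proportions must satisfy, on every 3 score x 3
item sub-table ("3-matrix"):

* single cancellation — proportions nondecreasing down each column
  (higher scoring groups do at least as well on every item) and across
  each row (easier items are answered correctly at least as often);
* double cancellation (Luce-Tukey) — on the anti-diagonals, if
  p(2,1) >= p(1,2) and p(3,2) >= p(2,3) then p(3,1) >= p(1,3), and the
  mirror-image implication with the inequalities reversed.

Observed proportions carry binomial sampling noise, so the check is
Bayesian: each 3-matrix gets a posterior over its nine true proportions
with independent binomial likelihoods and a uniform prior truncated to
the axiom-satisfying region, sampled by a single-site independence
Metropolis-Hastings chain. A cell is flagged when its empirical value
(the add-one smoothed proportion (y+1)/(n+2); see ``_empirical_estimate``)
falls outside the per-cell equal-tailed credible interval.
The headline statistic aggregates flags over many randomly sampled
3-matrices, weighting each cell by its score group's size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from conjointcheck.datagen import ResponseMatrix

__all__ = [
    "SummaryTable",
    "ThreeMatrix",
    "MCMCConfig",
    "CellCheck",
    "CheckSummary",
    "AxiomViolation",
    "adjacent_three_matrices",
    "build_summary_table",
    "sample_three_matrices",
    "ordinal_axiom_check",
    "bayes_check_three_matrix",
    "run_bcc",
]

logger = logging.getLogger(__name__)

# matrices per vectorized chain block; fixed so results do not depend on m
_CHUNK = 512


@dataclass(frozen=True)
class SummaryTable:
    """Score-group by item table of empirical proportions correct.

    ``item_order`` maps table column position -> original item index;
    columns are sorted by ascending marginal proportion correct (ascending
    easiness), ties broken by original index. Rows cover the observed
    interior sum scores only.
    """

    scores: np.ndarray  # ascending interior sum scores, length S
    row_counts: np.ndarray  # persons per score group, length S
    item_order: np.ndarray  # permutation of original item indices, length J
    cell_counts: np.ndarray  # S x J counts of correct responses, table order
    cell_props: np.ndarray  # S x J proportions, table order
    item_labels: tuple[str, ...] = ()

    @property
    def n_rows(self) -> int:
        return self.scores.size

    @property
    def n_cols(self) -> int:
        return self.item_order.size

    def to_frame(self) -> pd.DataFrame:
        labels = [self.item_labels[j] for j in self.item_order] if self.item_labels else list(self.item_order)
        df = pd.DataFrame(self.cell_props, columns=labels)
        df.insert(0, "sum_score", self.scores)
        df.insert(1, "n", self.row_counts)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ThreeMatrix:
    """One 3 score-group x 3 item sub-table, the unit of a cancellation check."""

    row_scores: np.ndarray  # 3 strictly increasing sum scores
    col_items: np.ndarray  # 3 increasing table-column positions
    counts: np.ndarray  # 3x3 correct-response counts
    trials: np.ndarray  # 3 row totals n_s

    @property
    def props(self) -> np.ndarray:
        return self.counts / self.trials[:, None]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings for the order-constrained posterior sampler."""

    burn_in: int = 500
    kept_draws: int = 2000
    credible_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kept_draws < 200:
            raise ValueError("kept_draws must be >= 200")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        if not 0 < self.credible_level < 1:
            raise ValueError("credible_level must be in (0, 1)")


@dataclass(frozen=True)
class CellCheck:
    """Credible-interval verdict for one cell of one 3-matrix.

    ``empirical_p`` is the cell's add-one smoothed proportion
    (y+1)/(n+2); ``violated`` holds exactly when it falls outside
    [ci_lo, ci_hi].
    """

    row: int
    col: int
    ci_lo: float
    ci_hi: float
    empirical_p: float
    violated: bool
    weight: int


@dataclass(frozen=True)
class CheckSummary:
    """Aggregate violation proportions over all checked cells."""

    weighted_prop: float
    unweighted_prop: float
    n_matrices: int
    cells: tuple[CellCheck, ...] = ()

    def to_json(self, path: str | Path | None = None, config: dict | None = None) -> str:
        payload: dict = {
            "weighted_prop": self.weighted_prop,
            "unweighted_prop": self.unweighted_prop,
            "n_matrices": self.n_matrices,
        }
        if config:
            payload["config"] = config
        if self.cells:
            payload["cells"] = [vars(c) for c in self.cells]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


class AxiomViolation(NamedTuple):
    """A failed deterministic axiom inequality on a 3-matrix of proportions."""

    axiom: str  # "single" or "double"
    cells: tuple[tuple[int, int], ...]  # (row, col) positions involved
    description: str


def build_summary_table(data: ResponseMatrix) -> SummaryTable:
    """Tabulate proportion correct by interior sum-score group and item.

    Persons with zero or perfect scores are dropped (they are uninformative
    for ordering). Requires at least 3 items and 3 distinct interior scores.
    """
    if data.j < 3:
        raise ValueError("need at least 3 items")
    scores = data.sum_scores
    interior = (scores > 0) & (scores < data.j)
    Xi = data.X[interior]
    si = scores[interior]
    uniq = np.unique(si)
    if uniq.size < 3:
        raise ValueError(
            f"need at least 3 distinct interior sum-score groups, found {uniq.size}"
        )
    # marginal proportion correct over all persons; stable sort breaks ties
    # by original column index
    marginal = data.X.mean(axis=0)
    order = np.argsort(marginal, kind="stable")
    counts = np.zeros((uniq.size, data.j), dtype=np.int64)
    row_counts = np.zeros(uniq.size, dtype=np.int64)
    for r, s in enumerate(uniq):
        rows = Xi[si == s]
        row_counts[r] = rows.shape[0]
        counts[r] = rows.sum(axis=0)
    counts = counts[:, order]
    props = counts / row_counts[:, None]
    return SummaryTable(
        scores=uniq.astype(np.int64),
        row_counts=row_counts,
        item_order=order,
        cell_counts=counts,
        cell_props=props,
        item_labels=tuple(data.item_labels),
    )


def _sample_indices(
    n_rows: int, n_cols: int, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """m independent uniform draws of 3 distinct rows and 3 distinct columns."""
    # the 3 smallest entries of a random uniform vector index a uniform
    # 3-subset; done as one batch for speed
    rows = np.sort(np.argpartition(rng.random((m, n_rows)), 2, axis=1)[:, :3], axis=1)
    cols = np.sort(np.argpartition(rng.random((m, n_cols)), 2, axis=1)[:, :3], axis=1)
    return rows.astype(np.int64), cols.astype(np.int64)


def sample_three_matrices(
    table: SummaryTable, m: int, seed: int | np.random.SeedSequence = 0
) -> list[ThreeMatrix]:
    """Draw ``m`` random 3-matrices (uniform over row and column triples)."""
    if m <= 0:
        raise ValueError("m must be positive")
    if table.n_rows < 3 or table.n_cols < 3:
        raise ValueError("summary table must have at least 3 rows and 3 columns")
    rng = np.random.default_rng(seed)
    rows, cols = _sample_indices(table.n_rows, table.n_cols, m, rng)
    out = []
    for i in range(m):
        r, c = rows[i], cols[i]
        out.append(
            ThreeMatrix(
                row_scores=table.scores[r],
                col_items=c.copy(),
                counts=table.cell_counts[np.ix_(r, c)],
                trials=table.row_counts[r],
            )
        )
    return out


def adjacent_three_matrices(table: SummaryTable) -> list[ThreeMatrix]:
    """Enumerate every 3-matrix of adjacent score rows and adjacent columns.

    The deterministic alternative to random sampling: all
    (rows-2) x (cols-2) contiguous 3x3 windows of the summary table.
    Random sampling over all row/column triples is the stricter and
    default mode; this enumeration is provided for comparison.
    """
    if table.n_rows < 3 or table.n_cols < 3:
        raise ValueError("summary table must have at least 3 rows and 3 columns")
    out = []
    for r in range(table.n_rows - 2):
        rows = np.arange(r, r + 3)
        for c in range(table.n_cols - 2):
            cols = np.arange(c, c + 3)
            out.append(
                ThreeMatrix(
                    row_scores=table.scores[rows],
                    col_items=cols,
                    counts=table.cell_counts[np.ix_(rows, cols)],
                    trials=table.row_counts[rows],
                )
            )
    return out


def ordinal_axiom_check(tm: ThreeMatrix) -> list[AxiomViolation]:
    """Deterministically check the observed proportions against the axioms.

    Single cancellation: proportions nondecreasing down every column and
    across every row (all ordered pairs reported). Double cancellation
    (classical Luce-Tukey, both orientations): if the two anti-diagonal
    antecedent inequalities hold, the corner conclusion must hold too.
    All inequalities are weak — ties never count as violations.
    """
    p = tm.props
    s = tm.row_scores
    out: list[AxiomViolation] = []
    for c in range(3):
        for r1 in range(3):
            for r2 in range(r1 + 1, 3):
                if p[r1, c] > p[r2, c]:
                    out.append(
                        AxiomViolation(
                            "single",
                            ((r1, c), (r2, c)),
                            f"p(score {s[r1]}, col {c}) = {p[r1, c]:.3f} > "
                            f"p(score {s[r2]}, col {c}) = {p[r2, c]:.3f}",
                        )
                    )
    for r in range(3):
        for c1 in range(3):
            for c2 in range(c1 + 1, 3):
                if p[r, c1] > p[r, c2]:
                    out.append(
                        AxiomViolation(
                            "single",
                            ((r, c1), (r, c2)),
                            f"p(score {s[r]}, col {c1}) = {p[r, c1]:.3f} > "
                            f"p(score {s[r]}, col {c2}) = {p[r, c2]:.3f}",
                        )
                    )
    if p[1, 0] >= p[0, 1] and p[2, 1] >= p[1, 2] and p[2, 0] < p[0, 2]:
        out.append(
            AxiomViolation(
                "double",
                ((1, 0), (0, 1), (2, 1), (1, 2), (2, 0), (0, 2)),
                f"antecedents hold but p(score {s[2]}, col 0) = {p[2, 0]:.3f} < "
                f"p(score {s[0]}, col 2) = {p[0, 2]:.3f}",
            )
        )
    if p[0, 1] >= p[1, 0] and p[1, 2] >= p[2, 1] and p[0, 2] < p[2, 0]:
        out.append(
            AxiomViolation(
                "double",
                ((0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)),
                f"antecedents hold but p(score {s[0]}, col 2) = {p[0, 2]:.3f} < "
                f"p(score {s[2]}, col 0) = {p[2, 0]:.3f}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# order-constrained posterior sampler (vectorized across 3-matrices)
# ---------------------------------------------------------------------------


def _feasible_after_update(pi: np.ndarray, r: int, c: int) -> np.ndarray:
    """Constraint satisfaction mask after changing cell (r, c) only.

    ``pi`` has shape (M, 3, 3). Only constraints touching (r, c) need
    rechecking: row/column monotonicity through the cell plus the two
    double-cancellation implications (which involve only off-diagonal
    cells, but are cheap enough to evaluate unconditionally).
    """
    ok = np.ones(pi.shape[0], dtype=bool)
    col = pi[:, :, c]
    if r > 0:
        ok &= col[:, r - 1] <= col[:, r]
    if r < 2:
        ok &= col[:, r] <= col[:, r + 1]
    row = pi[:, r, :]
    if c > 0:
        ok &= row[:, c - 1] <= row[:, c]
    if c < 2:
        ok &= row[:, c] <= row[:, c + 1]
    v1 = (pi[:, 1, 0] >= pi[:, 0, 1]) & (pi[:, 2, 1] >= pi[:, 1, 2]) & (pi[:, 2, 0] < pi[:, 0, 2])
    v2 = (pi[:, 0, 1] >= pi[:, 1, 0]) & (pi[:, 1, 2] >= pi[:, 2, 1]) & (pi[:, 0, 2] < pi[:, 2, 0])
    return ok & ~v1 & ~v2


def satisfies_axioms(pi: np.ndarray) -> np.ndarray:
    """Full feasibility (all single + double cancellation constraints), batched.

    ``pi`` may be (3, 3) or (M, 3, 3); returns a scalar bool or (M,) mask.
    """
    single = pi.ndim == 2
    if single:
        pi = pi[None]
    ok = np.all(np.diff(pi, axis=1) >= 0, axis=(1, 2))
    ok &= np.all(np.diff(pi, axis=2) >= 0, axis=(1, 2))
    v1 = (pi[:, 1, 0] >= pi[:, 0, 1]) & (pi[:, 2, 1] >= pi[:, 1, 2]) & (pi[:, 2, 0] < pi[:, 0, 2])
    v2 = (pi[:, 0, 1] >= pi[:, 1, 0]) & (pi[:, 1, 2] >= pi[:, 2, 1]) & (pi[:, 0, 2] < pi[:, 2, 0])
    ok &= ~(v1 | v2)
    return bool(ok[0]) if single else ok


def _constrained_posterior_draws(
    counts: np.ndarray,
    trials: np.ndarray,
    cfg: MCMCConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Kept draws from the axiom-constrained posterior, shape (K, M, 3, 3).

    ``counts`` is (M, 3, 3), ``trials`` (M, 3). Runs M independent
    single-site independence MH chains in lockstep. The proposal for cell
    (r, c) is its unconstrained Beta(y+1, n-y+1) posterior; because the
    target is that same product of Betas truncated to the axiom region,
    the MH acceptance probability reduces to the indicator that the
    proposed matrix is feasible.
    """
    M = counts.shape[0]
    A = counts + 1.0
    B = trials[:, :, None] - counts + 1.0
    # initialize at the per-matrix pooled proportion: constant matrices
    # satisfy every weak inequality, so the start is always feasible
    pbar = counts.sum(axis=(1, 2)) / (3.0 * trials.sum(axis=1))
    pi = np.repeat(pbar[:, None, None], 3, axis=1).repeat(3, axis=2).copy()
    n_sweeps = cfg.burn_in + cfg.kept_draws
    kept = np.empty((cfg.kept_draws, M, 3, 3), dtype=np.float32)
    accepts = np.zeros(M, dtype=np.int64)
    cells = [(r, c) for r in range(3) for c in range(3)]
    for sweep in range(n_sweeps):
        for r, c in cells:
            prop = rng.beta(A[:, r, c], B[:, r, c])
            cur = pi[:, r, c].copy()
            pi[:, r, c] = prop
            ok = _feasible_after_update(pi, r, c)
            pi[~ok, r, c] = cur[~ok]
            if sweep >= cfg.burn_in:
                accepts += ok
        if sweep >= cfg.burn_in:
            kept[sweep - cfg.burn_in] = pi
    if np.any(accepts == 0):
        bad = int(np.flatnonzero(accepts == 0)[0])
        raise RuntimeError(
            "constrained-posterior sampler accepted no proposals after burn-in "
            f"for 3-matrix {bad} (counts={counts[bad].tolist()}, "
            f"trials={trials[bad].tolist()}); chain is degenerate"
        )
    return kept


def _constrained_posterior_ci(
    counts: np.ndarray,
    trials: np.ndarray,
    cfg: MCMCConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equal-tailed per-cell credible intervals; returns (lo, hi, posterior mean)."""
    kept = _constrained_posterior_draws(counts, trials, cfg, rng)
    alpha = 1.0 - cfg.credible_level
    lo, hi = np.quantile(kept, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    return lo.astype(float), hi.astype(float), kept.mean(axis=0, dtype=np.float64)


def _batch_check(
    counts: np.ndarray,
    trials: np.ndarray,
    cfg: MCMCConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Violation flags and CIs for a stack of 3-matrices, chunked for memory."""
    rng = np.random.default_rng(seed)
    M = counts.shape[0]
    lo = np.empty((M, 3, 3))
    hi = np.empty((M, 3, 3))
    for start in range(0, M, _CHUNK):
        sl = slice(start, min(start + _CHUNK, M))
        lo[sl], hi[sl], _ = _constrained_posterior_ci(counts[sl], trials[sl], cfg, rng)
    p_emp = _empirical_estimate(counts, trials)
    violated = (p_emp < lo) | (p_emp > hi)
    return violated, lo, hi


def _empirical_estimate(counts: np.ndarray, trials: np.ndarray) -> np.ndarray:
    """Add-one smoothed cell proportion (y + 1) / (n + 2).

    This is the posterior mean of the cell proportion under the same
    uniform prior the constrained model uses. The smoothing matters at the
    boundary: a raw proportion of exactly 0 or 1 lies outside any credible
    interval built from continuous posterior draws, so comparing raw
    proportions would flag every all-correct/all-incorrect cell regardless
    of whether the axioms constrain it. The smoothed estimate keeps such
    cells in play while flagging them only when the order constraints
    genuinely pull the posterior away from the observed value.
    """
    return (counts + 1.0) / (trials[:, :, None] + 2.0)


def bayes_check_three_matrix(tm: ThreeMatrix, cfg: MCMCConfig) -> list[CellCheck]:
    """Run the constrained-posterior check on a single 3-matrix."""
    if np.any(tm.trials < 1):
        raise ValueError("every row of a 3-matrix needs at least one person")
    counts = tm.counts[None].astype(float)
    trials = tm.trials[None].astype(float)
    violated, lo, hi = _batch_check(counts, trials, cfg, cfg.seed)
    p_emp = _empirical_estimate(counts, trials)
    return [
        CellCheck(
            row=r,
            col=c,
            ci_lo=float(lo[0, r, c]),
            ci_hi=float(hi[0, r, c]),
            empirical_p=float(p_emp[0, r, c]),
            violated=bool(violated[0, r, c]),
            weight=int(tm.trials[r]),
        )
        for r in range(3)
        for c in range(3)
    ]


def run_bcc(
    data: ResponseMatrix,
    m: int = 5000,
    cfg: MCMCConfig | None = None,
    keep_cells: bool = False,
    mode: str = "random",
) -> CheckSummary:
    """Full pipeline: summary table -> 3-matrices -> Bayesian checks.

    With the default ``mode="random"``, ``m`` row/column triples are drawn
    uniformly; ``mode="adjacent"`` instead enumerates every contiguous 3x3
    window of the table (``m`` is ignored). Returns the weighted violation
    proportion (cell flags weighted by the cell's score-group size) and the
    unweighted cell-level mean. With ``keep_cells`` the per-cell verdicts
    are retained on the summary.
    """
    cfg = cfg or MCMCConfig()
    table = build_summary_table(data)
    ss = np.random.SeedSequence(cfg.seed)
    seed_sample, seed_chain = ss.spawn(2)
    if mode == "random":
        rng = np.random.default_rng(seed_sample)
        rows, cols = _sample_indices(table.n_rows, table.n_cols, m, rng)
    elif mode == "adjacent":
        if table.n_rows < 3 or table.n_cols < 3:
            raise ValueError("summary table must have at least 3 rows and 3 columns")
        base_r = np.arange(table.n_rows - 2)
        base_c = np.arange(table.n_cols - 2)
        rr, cc = np.meshgrid(base_r, base_c, indexing="ij")
        rows = rr.ravel()[:, None] + np.arange(3)[None, :]
        cols = cc.ravel()[:, None] + np.arange(3)[None, :]
        m = rows.shape[0]
    else:
        raise ValueError('mode must be "random" or "adjacent"')
    counts = np.empty((m, 3, 3))
    trials = np.empty((m, 3))
    for i in range(m):
        counts[i] = table.cell_counts[np.ix_(rows[i], cols[i])]
        trials[i] = table.row_counts[rows[i]]
    violated, lo, hi = _batch_check(counts, trials, cfg, seed_chain)
    weights = np.broadcast_to(trials[:, :, None], violated.shape)
    weighted = float((weights * violated).sum() / weights.sum())
    unweighted = float(violated.mean())
    cells: tuple[CellCheck, ...] = ()
    if keep_cells:
        p_emp = _empirical_estimate(counts, trials)
        cells = tuple(
            CellCheck(
                row=int(rows[i][r]),
                col=int(cols[i][c]),
                ci_lo=float(lo[i, r, c]),
                ci_hi=float(hi[i, r, c]),
                empirical_p=float(p_emp[i, r, c]),
                violated=bool(violated[i, r, c]),
                weight=int(trials[i, r]),
            )
            for i in range(m)
            for r in range(3)
            for c in range(3)
        )
    return CheckSummary(
        weighted_prop=weighted,
        unweighted_prop=unweighted,
        n_matrices=m,
        cells=cells,
    )
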