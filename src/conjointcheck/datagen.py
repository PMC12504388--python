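"""Simulation of dichotomous item responses under Rasch and 2PL models.

Person abilities (theta) and item difficulties (b) live on a common logit
scale; discriminations (a) are unitless slopes. The Rasch model is the
special case a_j = 1 for every item, in which the log-odds of a correct
response is the additive difference theta_i - b_j. The non-Rasch generator
is the standard two-parameter logistic with log-odds a_j (theta_i - b_j).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PersonParams",
    "ItemParams",
    "ResponseMatrix",
    "parse_disc_spec",
    "draw_person_params",
    "draw_item_params",
    "simulate_responses",
]


@dataclass(frozen=True)
class PersonParams:
    """Latent abilities theta_i, in logit units."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if theta.ndim != 1 or theta.size < 1:
            raise ValueError("theta must be a non-empty 1-D vector")
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta must be finite")

    @property
    def n(self) -> int:
        return self.theta.size


@dataclass(frozen=True)
class ItemParams:
    """Item difficulties b_j (logits) and discriminations a_j (> 0)."""

    difficulty: np.ndarray
    discrimination: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.difficulty, dtype=float)
        a = np.asarray(self.discrimination, dtype=float)
        object.__setattr__(self, "difficulty", b)
        object.__setattr__(self, "discrimination", a)
        if b.ndim != 1 or b.size < 3:
            raise ValueError("need at least 3 items (3-matrices require >= 3)")
        if a.shape != b.shape:
            raise ValueError("difficulty and discrimination lengths differ")
        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(a))):
            raise ValueError("item parameters must be finite")
        if np.any(a <= 0):
            raise ValueError("discriminations must be positive")

    @property
    def j(self) -> int:
        return self.difficulty.size


@dataclass(frozen=True)
class ResponseMatrix:
    """N x J matrix of 0/1 responses with optional person/item labels."""

    X: np.ndarray
    item_labels: Sequence[str] = field(default=None)  # type: ignore[assignment]
    person_labels: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        X = np.asarray(self.X)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("responses must all be 0 or 1, with no missing entries")
        X = X.astype(np.int8)
        object.__setattr__(self, "X", X)
        if self.item_labels is None:
            object.__setattr__(
                self, "item_labels", [f"item{j + 1}" for j in range(X.shape[1])]
            )
        elif len(self.item_labels) != X.shape[1]:
            raise ValueError("item_labels length must equal the number of columns")
        if self.person_labels is not None and len(self.person_labels) != X.shape[0]:
            raise ValueError("person_labels length must equal the number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def j(self) -> int:
        return self.X.shape[1]

    @property
    def sum_scores(self) -> np.ndarray:
        return self.X.sum(axis=1)

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV: header of item labels, one row per person."""
        pd.DataFrame(self.X, columns=list(self.item_labels)).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseMatrix":
        """Read a response matrix CSV (an optional leading "id" column is dropped)."""
        df = pd.read_csv(path)
        if df.shape[1] and df.columns[0].lower() in ("id", "person", "person_id"):
            person_labels = df.iloc[:, 0].astype(str).tolist()
            df = df.iloc[:, 1:]
        else:
            person_labels = None
        if df.isna().any().any():
            r, c = next(zip(*np.nonzero(df.isna().to_numpy())))
            raise ValueError(f"missing value at row {r + 1}, column '{df.columns[c]}'")
        values = df.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell {values[r, c]!r} at row {r + 1}, column '{df.columns[c]}'"
            )
        return cls(values, item_labels=list(df.columns), person_labels=person_labels)


def parse_disc_spec(spec) -> tuple[float, float] | str:
    """Normalize a discrimination spec to "rasch" or a (lo, hi) uniform range.

    Accepts "rasch", an (lo, hi) pair, or strings like "uniform(0.8,1.2)".
    """
    if isinstance(spec, str):
        s = spec.strip().lower()
        if s == "rasch":
            return "rasch"
        if s.startswith(("uniform(", "unif(", "u(")) and s.endswith(")"):
            inner = s[s.index("(") + 1 : -1]
            lo, hi = (float(v) for v in inner.split(","))
            return _check_bounds(lo, hi)
        raise ValueError(f"unrecognized discrimination spec: {spec!r}")
    lo, hi = spec
    return _check_bounds(float(lo), float(hi))


def _check_bounds(lo: float, hi: float) -> tuple[float, float]:
    if not (0 < lo <= hi):
        raise ValueError(f"uniform discrimination bounds must satisfy 0 < lo <= hi, got ({lo}, {hi})")
    return (lo, hi)


def draw_person_params(
    n: int, mean: float = 0.0, sd: float = 1.0, seed: int | np.random.SeedSequence = 0
) -> PersonParams:
    """Draw ``n`` abilities i.i.d. from Normal(mean, sd**2)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    return PersonParams(rng.normal(mean, sd, size=n))


def draw_item_params(
    j: int,
    diff_mean: float = 0.0,
    diff_scale: float = 0.25,
    disc="rasch",
    seed: int | np.random.SeedSequence = 0,
    scale: str = "var",
) -> ItemParams:
    """Draw ``j`` item parameters.

    Difficulties are Normal(diff_mean, diff_scale) where ``scale`` says whether
    ``diff_scale`` is a variance (``"var"``, the default) or a standard
    deviation (``"sd"``) — published difficulty distributions are printed in
    both parameterizations, so the caller states which one it has.
    Discriminations are all 1 for ``disc="rasch"``, else i.i.d. Uniform(lo, hi).
    """
    if j < 3:
        raise ValueError("need at least 3 items")
    if scale not in ("var", "sd"):
        raise ValueError("scale must be 'var' or 'sd'")
    if diff_scale < 0:
        raise ValueError("difficulty scale must be nonnegative")
    sd = float(np.sqrt(diff_scale)) if scale == "var" else float(diff_scale)
    spec = parse_disc_spec(disc)
    rng = np.random.default_rng(seed)
    b = rng.normal(diff_mean, sd, size=j)
    if spec == "rasch":
        a = np.ones(j)
    else:
        lo, hi = spec
        a = rng.uniform(lo, hi, size=j)
    return ItemParams(b, a)


def response_probabilities(persons: PersonParams, items: ItemParams) -> np.ndarray:
    """N x J matrix of P(X_ij = 1) = logistic(a_j (theta_i - b_j))."""
    logit = items.discrimination[None, :] * (
        persons.theta[:, None] - items.difficulty[None, :]
    )
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_responses(
    persons: PersonParams,
    items: ItemParams,
    seed: int | np.random.SeedSequence = 0,
) -> ResponseMatrix:
    """Simulate independent Bernoulli responses from the 2PL/Rasch probabilities."""
    p = response_probabilities(persons, items)
    rng = np.random.default_rng(seed)
    X = (rng.random(p.shape) < p).astype(np.int8)
    return ResponseMatrix(X)


def write_dataset(
    data: ResponseMatrix,
    persons: PersonParams,
    items: ItemParams,
    seed: int,
    csv_path: str | Path,
) -> Path:
    """Write responses as CSV plus a JSON sidecar of generating parameters.

    The sidecar (same stem, ``.params.json``) records theta, b, a and the
    seed so any simulated dataset is reproducible from its own outputs.
    """
    csv_path = Path(csv_path)
    data.to_csv(csv_path)
    sidecar = csv_path.with_suffix(".params.json")
    sidecar.write_text(
        json.dumps(
            {
                "seed": seed,
                "theta": persons.theta.tolist(),
                "difficulty": items.difficulty.tolist(),
                "discrimination": items.discrimination.tolist(),
            },
            indent=2,
        )
    )
    return sidecar
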