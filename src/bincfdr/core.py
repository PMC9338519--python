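"""Binary conditional FDR ("Binary cFDR").

Transforms GWAS p-values paired with a binary covariate q (e.g. overlap with a
functional annotation) into *v-values*: quantities that are uniform on (0, 1]
under the null hypothesis and therefore usable in any standard multiple-testing
procedure, but which borrow strength from q so that SNPs in the covariate
stratum enriched for signal attain smaller values.

The construction follows the conditional-FDR recipe for two-point covariates.
For each SNP i with observed pair ``(p_i, q_i)`` a rejection region

    L(p0, p1) = (P <= p0, Q = 0)  union  (P <= p1, Q = 1)

is chosen so that the two thresholds equalise the estimated density ratio
``f(p, q) / f0(p, q)`` between the two covariate strata, with the coordinate of
the observed stratum pinned at ``p_i``.  The v-value is the null mass of this
region,

    v_i = p0 * (1 - q0) + p1 * q0,        q0 = Pr(Q = 1 | H0),

estimated with leave-one-group-out empirical CDFs so that rejection rules are
never fit on the SNPs they judge.

All estimation here is deterministic: identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Smallest value a p- or v-value may take (smallest positive normal double).
#: Emitted v-values are floored here so downstream -log10 / BH never see 0.
P_FLOOR = float(np.finfo(np.float64).tiny)

__all__ = [
    "P_FLOOR",
    "SummaryTable",
    "StratumModel",
    "RejectionRegion",
    "VValueResult",
    "estimate_null_covariate_rate",
    "fit_stratum_model",
    "cfdr_ratio",
    "monotone_cfdr_ratio",
    "solve_matched_threshold",
    "v_value",
    "binary_cfdr",
    "iterate_cfdr",
    "bh_adjust",
]


def _format_rows(idx: np.ndarray, limit: int = 5) -> str:
    shown = ", ".join(str(i) for i in idx[:limit])
    more = f" (+{idx.size - limit} more)" if idx.size > limit else ""
    return shown + more


@dataclass
class SummaryTable:
    """Per-SNP input records: p-value, binary covariate and fold label.

    Parameters
    ----------
    p
        Association p-values, each in (0, 1].  Exact zeros are rejected; clamp
        them to :data:`P_FLOOR` beforehand (see ``from_dataframe``) if they are
        known underflows.
    q
        Binary covariate, each entry 0 or 1.
    group
        Fold label used for leave-one-group-out estimation — chromosome for
        real data, LD block for simulations.  Treated as an opaque partition.
    snp_id, chrom, pos
        Optional identifiers carried through to output.
    """

    p: np.ndarray
    q: np.ndarray
    group: np.ndarray
    snp_id: np.ndarray | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.q = np.asarray(self.q)
        self.group = np.asarray(self.group)
        if self.p.ndim != 1:
            raise ValueError("p must be one-dimensional")
        if not (self.p.shape == self.q.shape == self.group.shape):
            raise ValueError(
                f"column lengths differ: p={self.p.size}, q={self.q.size}, "
                f"group={self.group.size}"
            )
        bad_p = np.flatnonzero(~((self.p > 0.0) & (self.p <= 1.0)))
        if bad_p.size:
            raise ValueError(
                f"column 'p': values outside (0, 1] at rows {_format_rows(bad_p)}"
            )
        bad_q = np.flatnonzero(~np.isin(self.q, (0, 1)))
        if bad_q.size:
            raise ValueError(
                f"column 'q': values not in {{0, 1}} at rows {_format_rows(bad_q)}"
            )
        self.q = self.q.astype(np.int8)
        if self.snp_id is None:
            self.snp_id = np.array([f"snp_{i}" for i in range(self.p.size)])
        else:
            self.snp_id = np.asarray(self.snp_id)

    @classmethod
    def from_dataframe(
        cls,
        df,
        q_col: str = "q",
        group_col: str = "group",
        allow_p_clamp: bool = False,
    ) -> "SummaryTable":
        """Build and validate a table from a pandas DataFrame.

        With ``allow_p_clamp`` p-values equal to 0 are clamped to
        :data:`P_FLOOR` (use for known numerical underflows); otherwise they
        are an error naming the offending rows.
        """
        for col in ("snp", "p", q_col, group_col):
            if col not in df.columns:
                raise ValueError(f"missing required column '{col}'")
        p = df["p"].to_numpy(dtype=np.float64)
        if allow_p_clamp:
            p = np.where(p == 0.0, P_FLOOR, p)
        return cls(
            p=p,
            q=df[q_col].to_numpy(),
            group=df[group_col].to_numpy(),
            snp_id=df["snp"].to_numpy(),
            chrom=df["chrom"].to_numpy() if "chrom" in df.columns else None,
            pos=df["pos"].to_numpy() if "pos" in df.columns else None,
        )

    def to_dataframe(self):
        import pandas as pd

        data = {"snp": self.snp_id, "p": self.p, "q": self.q, "group": self.group}
        if self.chrom is not None:
            data["chrom"] = self.chrom
        if self.pos is not None:
            data["pos"] = self.pos
        return pd.DataFrame(data)

    def subset(self, mask: np.ndarray) -> "SummaryTable":
        return SummaryTable(
            p=self.p[mask],
            q=self.q[mask],
            group=self.group[mask],
            snp_id=self.snp_id[mask],
            chrom=None if self.chrom is None else self.chrom[mask],
            pos=None if self.pos is None else self.pos[mask],
        )

    def __len__(self) -> int:
        return int(self.p.size)

    @property
    def n_groups(self) -> int:
        return int(np.unique(self.group).size)


def _upper_hull(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertices of the least concave majorant of points sorted by x."""
    hx: list[float] = []
    hy: list[float] = []
    for xi, yi in zip(x, y):
        while len(hx) >= 2 and (
            (hx[-1] - hx[-2]) * (yi - hy[-2]) - (hy[-1] - hy[-2]) * (xi - hx[-2])
        ) >= 0.0:
            hx.pop()
            hy.pop()
        hx.append(float(xi))
        hy.append(float(yi))
    return np.asarray(hx), np.asarray(hy)


class EmpiricalCdf:
    """Continuity-corrected ECDF of one covariate stratum, plus its concave hull.

    The step estimate is ``F(x) = (#{p_j <= x} + 1) / (m + 1)`` — strictly
    positive for every x, so density ratios built from it are finite; the +1
    correction also accounts for the held-out SNP itself, which is excluded
    from its own training fold.

    ``concave(x)`` evaluates the least concave majorant of the step function
    anchored at (0, 0) and (1, 1).  This is the Grenander-type CDF estimate
    under the working assumption that the p-value density within a stratum is
    nonincreasing; it makes the ratio ``p / F(p)`` nondecreasing in p, which
    the threshold matching relies on.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        self.m = int(values.size)
        self.knots, counts = np.unique(values, return_counts=True)
        self.cum = np.cumsum(counts)
        # hull points: origin, corrected ECDF at each knot, and (1, 1)
        px = np.concatenate(([0.0], self.knots))
        py = np.concatenate(([0.0], (self.cum + 1.0) / (self.m + 1.0)))
        if px[-1] < 1.0:
            px = np.concatenate((px, [1.0]))
            py = np.concatenate((py, [1.0]))
        self.vx, self.vy = _upper_hull(px, py)

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float64)
        j = np.searchsorted(self.knots, x, side="right")
        cnt = np.where(j > 0, self.cum[np.maximum(j - 1, 0)], 0)
        out = (cnt + 1.0) / (self.m + 1.0)
        return out if out.ndim else float(out)

    def concave(self, x):
        """Least concave majorant, linearly interpolated between hull vertices."""
        x = np.asarray(x, dtype=np.float64)
        out = np.interp(x, self.vx, self.vy)
        return out if out.ndim else float(out)


@dataclass
class StratumModel:
    """Everything needed to evaluate the two-stratum density-ratio chain.

    Holds per-stratum ECDFs of p, stratum sizes, the marginal covariate rate
    Pr(Q=1) and the estimated null covariate rate q0 = Pr(Q=1 | H0) — all fit
    on a training fold that excludes the SNPs being scored.
    """

    ecdf_0: EmpiricalCdf | None
    ecdf_1: EmpiricalCdf | None
    m_0: int
    m_1: int
    marginal_q: float
    null_q: float

    def stratum_size(self, stratum: int) -> int:
        return self.m_1 if stratum == 1 else self.m_0

    def ecdf(self, stratum: int) -> EmpiricalCdf:
        e = self.ecdf_1 if stratum == 1 else self.ecdf_0
        if e is None:
            raise ValueError(
                f"stratum {stratum} is empty in the training fold; the covariate "
                "is uninformative here — use the degenerate path (v = p)"
            )
        return e

    def null_rate(self, stratum: int) -> float:
        return self.null_q if stratum == 1 else 1.0 - self.null_q

    def marginal(self, stratum: int) -> float:
        return self.marginal_q if stratum == 1 else 1.0 - self.marginal_q


@dataclass(frozen=True)
class RejectionRegion:
    """Thresholds (p0, p1) of the region (P<=p0, Q=0) ∪ (P<=p1, Q=1)."""

    p0: float
    p1: float

    def __post_init__(self):
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p1 <= 1.0):
            raise ValueError(f"region coordinates outside [0,1]: {self}")


@dataclass
class VValueResult:
    """Per-SNP v-values and their BH adjustment for one iteration."""

    v: np.ndarray
    fdr: np.ndarray
    iteration: int


def estimate_null_covariate_rate(training: SummaryTable) -> float:
    """Estimate q0 = Pr(Q = 1 | H0) from a training fold.

    Since P | H0 is uniform on (0, 1] and true associations are rare with
    small p, the region p > 1/2 is overwhelmingly null; q0 is estimated as the
    covariate-positive fraction there.  Falls back to the overall fraction if
    no training SNP has p > 1/2.
    """
    if len(training) == 0:
        raise ValueError("empty training fold: cannot estimate null covariate rate")
    null_region = training.p > 0.5
    if null_region.any():
        return float(np.mean(training.q[null_region]))
    return float(np.mean(training.q))


def fit_stratum_model(training: SummaryTable) -> StratumModel:
    """Fit per-stratum ECDFs and covariate rates on a training fold."""
    if len(training) == 0:
        raise ValueError("empty training fold")
    in1 = training.q == 1
    p0 = training.p[~in1]
    p1 = training.p[in1]
    m_0, m_1 = int(p0.size), int(p1.size)
    return StratumModel(
        ecdf_0=EmpiricalCdf(p0) if m_0 else None,
        ecdf_1=EmpiricalCdf(p1) if m_1 else None,
        m_0=m_0,
        m_1=m_1,
        marginal_q=m_1 / (m_0 + m_1),
        null_q=estimate_null_covariate_rate(training),
    )


def cfdr_ratio(p, stratum: int, model: StratumModel):
    """Estimated ratio  Pr(P<=p | Q=s, H0)·Pr(Q=s | H0) / (Pr(P<=p | Q=s)·Pr(Q=s)).

    Uses the null approximation Pr(P<=p | Q=s, H0) ≈ p.  Strictly positive and
    finite for p in (0, 1]; vectorised over p.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p must lie in (0, 1]")
    if model.stratum_size(stratum) == 0:
        model.ecdf(stratum)  # raises with the degenerate-path message
    c = model.null_rate(stratum) / model.marginal(stratum)
    out = p * c / model.ecdf(stratum)(p)
    return out if out.ndim else float(out)


def _monotone_ratio(p: np.ndarray, stratum: int, model: StratumModel) -> np.ndarray:
    """Monotone envelope of the raw ratio: p·c/concave-hull-CDF(p).

    Concavifying the ECDF makes the ratio a continuous nondecreasing function
    of p (for a concave F through the origin, F(p)/p is nonincreasing), which
    stabilises the threshold matching: the raw step-function ratio is not
    monotone and, when the covariate carries no information, hovers around a
    constant, making its pointwise inversion ill-posed.
    """
    e = model.ecdf(stratum)
    c = model.null_rate(stratum) / model.marginal(stratum)
    return p * c / e.concave(p)


def monotone_cfdr_ratio(p, stratum: int, model: StratumModel):
    """Monotone-envelope version of :func:`cfdr_ratio`; the matching target."""
    p = np.atleast_1d(np.asarray(p, dtype=np.float64))
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p must lie in (0, 1]")
    out = _monotone_ratio(p, stratum, model)
    return out if out.size > 1 else float(out[0])


def _invert_ratio(targets: np.ndarray, stratum: int, model: StratumModel) -> np.ndarray:
    """Largest p in [0, 1] whose monotone-envelope ratio is <= target.

    On each linear hull segment F(p) = a + b·p the ratio p·c/F(p) inverts in
    closed form to p = t·a / (c − t·b); flats (the first hull segment, through
    the origin) resolve to their right end — the largest p achieving the
    level.  Clamps: a target below the smallest achievable ratio gives 0; a
    target at or above the ratio at p = 1 (which equals c) gives 1.
    """
    e = model.ecdf(stratum)
    c = model.null_rate(stratum) / model.marginal(stratum)
    targets = np.asarray(targets, dtype=np.float64)
    if c == 0.0:
        # No null mass in this stratum: the ratio is identically 0, every
        # threshold satisfies it, and the coordinate carries zero null weight.
        return np.ones_like(targets)
    vx, vy = e.vx, e.vy
    # ratio at hull vertices 1..K is nondecreasing (vx/vy nondecreasing)
    rv = vx[1:] * c / vy[1:]
    k = np.searchsorted(rv, targets, side="right")
    out = np.empty_like(targets)
    out[k == 0] = 0.0
    out[k == rv.size] = 1.0
    mid = (k > 0) & (k < rv.size)
    if np.any(mid):
        km = k[mid]  # hull vertex index of the segment's left end
        b = (vy[km + 1] - vy[km]) / (vx[km + 1] - vx[km])
        a = vy[km] - b * vx[km]
        t = targets[mid]
        out[mid] = np.clip(t * a / (c - t * b), vx[km], vx[km + 1])
    return out


def solve_matched_threshold(
    p_i: float, q_i: int, model: StratumModel
) -> RejectionRegion:
    """Find the rejection region for one SNP by matching density ratios.

    The coordinate of the observed stratum is pinned at ``p_i``; the opposite
    coordinate is the largest p whose monotone-envelope ratio in the opposite
    stratum does not exceed the (monotone) target ratio at ``p_i``.  If either
    stratum is empty in the training fold the covariate is uninformative and
    the degenerate region (p_i, p_i) — whose null mass is exactly p_i — is
    returned.
    """
    if not (0.0 < p_i <= 1.0):
        raise ValueError("p_i must lie in (0, 1]")
    if q_i not in (0, 1):
        raise ValueError("q_i must be 0 or 1")
    if model.stratum_size(0) == 0 or model.stratum_size(1) == 0:
        return RejectionRegion(p0=p_i, p1=p_i)
    target = _monotone_ratio(np.array([p_i]), q_i, model)
    p_star = float(_invert_ratio(target, 1 - q_i, model)[0])
    if q_i == 0:
        return RejectionRegion(p0=p_i, p1=p_star)
    return RejectionRegion(p0=p_star, p1=p_i)


def v_value(region: RejectionRegion, null_q: float) -> float:
    """Null mass of a rejection region:  p0·(1−q0) + p1·q0, floored into (0, 1]."""
    if not (0.0 <= null_q <= 1.0):
        raise ValueError("null_q must lie in [0, 1]")
    v = region.p0 * (1.0 - null_q) + region.p1 * null_q
    return float(min(max(v, P_FLOOR), 1.0))


def binary_cfdr(table: SummaryTable, iteration: int = 1) -> VValueResult:
    """Compute Binary cFDR v-values with leave-one-group-out estimation.

    For each group g the stratum model is fit on all SNPs *not* in g, and
    every SNP of g is scored against it.  Returns v in input order together
    with its BH adjustment.  Deterministic.
    """
    if table.n_groups < 2:
        raise ValueError(
            "fold removal requires at least 2 distinct groups "
            f"(got {table.n_groups})"
        )
    m = len(table)
    v = np.empty(m, dtype=np.float64)
    for g in np.unique(table.group):
        held_out = table.group == g
        model = fit_stratum_model(table.subset(~held_out))
        logger.debug(
            "fold %r: m0=%d m1=%d marginal_q=%.4g null_q=%.4g",
            g, model.m_0, model.m_1, model.marginal_q, model.null_q,
        )
        for s in (0, 1):
            idx = np.flatnonzero(held_out & (table.q == s))
            if idx.size == 0:
                continue
            if model.stratum_size(0) == 0 or model.stratum_size(1) == 0:
                # covariate constant in training: uninformative, v = p
                v[idx] = table.p[idx]
                continue
            targets = _monotone_ratio(table.p[idx], s, model)
            p_star = _invert_ratio(targets, 1 - s, model)
            if s == 0:
                v[idx] = table.p[idx] * (1.0 - model.null_q) + p_star * model.null_q
            else:
                v[idx] = p_star * (1.0 - model.null_q) + table.p[idx] * model.null_q
    v = np.clip(v, P_FLOOR, 1.0)
    fdr = bh_adjust(v)
    logger.info(
        "binary_cfdr iteration %d: m=%d, groups=%d, %d SNPs with fdr<0.05",
        iteration, m, table.n_groups, int(np.sum(fdr < 0.05)),
    )
    return VValueResult(v=v, fdr=fdr, iteration=iteration)


def iterate_cfdr(
    table: SummaryTable, covariates: Sequence[np.ndarray]
) -> list[VValueResult]:
    """Apply Binary cFDR iteratively over several binary covariates.

    Iteration k uses iteration k−1's v-values as the principal p-values
    (iteration 1 uses the input p) and the k-th covariate vector, in the
    caller-supplied order.  Returns the full per-iteration trace.
    """
    if len(covariates) == 0:
        raise ValueError("need at least one covariate vector")
    for k, q in enumerate(covariates):
        if np.asarray(q).shape != table.p.shape:
            raise ValueError(
                f"covariate {k} has length {np.asarray(q).size}, "
                f"expected {len(table)}"
            )
    results: list[VValueResult] = []
    p_current = table.p
    for k, q in enumerate(covariates):
        current = SummaryTable(
            p=p_current,
            q=q,
            group=table.group,
            snp_id=table.snp_id,
            chrom=table.chrom,
            pos=table.pos,
        )
        res = binary_cfdr(current, iteration=k + 1)
        results.append(res)
        p_current = res.v
    return results


def bh_adjust(v: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    v-values tolerate the slight positive dependence seen in GWAS, so the
    plain BH procedure applies.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(v <= 0.0) or np.any(v > 1.0):
        raise ValueError("values must lie in (0, 1]")
    return multipletests(v, method="fdr_bh")[1]
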