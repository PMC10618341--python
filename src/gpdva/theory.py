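"""Conditional moments of the additive genetic variance and its GPD components.

For QTL effects a ~ N(0, I) and a fixed genotype matrix X with score
covariance D = V + W + B, every component of

    V_A = a'Da = a'Va + a'Wa + a'Ba = V_g + C_w + C_b

is a Gaussian quadratic form, so its conditional moments follow from the
standard identities E[a'Ma] = trace(M), var[a'Ma] = 2 trace(M^2) and
cov[a'M1 a, a'M2 a] = 2 trace(M1 M2).  Because V is diagonal while W and B
have zero diagonals and disjoint supports, all three pairwise covariances
vanish, giving var[V_A|X] = var[V_g|X] + var[C_w|X] + var[C_b|X] exactly.

The standardized ratios b_w = C_w/V_g, b_b = C_b/V_g and b = b_w + b_b get
first-order (delta-method) approximations: E ~ 0 and
var[b_w|X] ~ 2 trace(W^2)/trace(V)^2 (likewise for b_b and b).  Those are
approximations, never exact; the Monte-Carlo sampler below is the reference
for their quality.  b and b_w are bounded below by -1 (positive
semidefiniteness of D), while b_b can fall below -1 when b_w > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .genotypes import DisequilibriumDecomposition, InvalidInputError

__all__ = [
    "RealizedComponents",
    "ConditionalMoments",
    "MonteCarloSummary",
    "SignAsymmetryEstimate",
    "realized_components",
    "conditional_moments",
    "b_lower_bound",
    "monte_carlo_moments",
    "sign_asymmetry_probability",
]

COMPONENTS = ("V_g", "C_w", "C_b", "C", "V_A", "b_w", "b_b", "b")


@dataclass(frozen=True)
class RealizedComponents:
    """Variance components and standardized ratios for one effect vector."""

    V_A: float
    V_g: float
    C_w: float
    C_b: float
    C: float
    b_w: float
    b_b: float
    b: float
    ratios_defined: bool


@dataclass(frozen=True)
class ConditionalMoments:
    """Exact moments of V_g, C_w, C_b, V_A and approximate moments of the b ratios."""

    E_Vg: float
    E_Cw: float
    E_Cb: float
    E_VA: float
    var_Vg: float
    var_Cw: float
    var_Cb: float
    var_VA: float
    E_bw: float
    E_bb: float
    E_b: float
    var_bw: float
    var_bb: float
    var_b: float
    ratios_defined: bool

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(eq=False)
class MonteCarloSummary:
    """Empirical moments of the realized components over sampled effect vectors."""

    n_samples: int
    seed: object
    stats: pd.DataFrame  # index: component, columns: mean/variance/skewness/kurtosis
    components: dict  # component name -> array of realizations
    n_undefined_ratios: int


@dataclass(frozen=True)
class SignAsymmetryEstimate:
    prob_negative: float
    se: float
    n_samples: int
    degenerate: bool


def realized_components(dec: DisequilibriumDecomposition, a: np.ndarray) -> RealizedComponents:
    """Quadratic forms V_A = a'Da, V_g = a'Va, C_w = a'Wa, C_b = a'Ba.

    The ratios b_w, b_b, b are NaN with ``ratios_defined=False`` when V_g = 0
    (all sampled QTL monomorphic), so aggregation can skip rather than fail.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (dec.n_loci,):
        raise InvalidInputError(f"effect vector length {a.size} does not match {dec.n_loci} loci")
    dii = np.diag(dec.D)
    V_g = float(dii @ (a * a))
    C_w = float(a @ dec.W @ a)
    C_b = float(a @ dec.B @ a)
    V_A = float(a @ dec.D @ a)
    C = C_w + C_b
    if V_g > 0:
        return RealizedComponents(V_A, V_g, C_w, C_b, C, C_w / V_g, C_b / V_g, C / V_g, True)
    return RealizedComponents(V_A, V_g, C_w, C_b, C, np.nan, np.nan, np.nan, False)


def conditional_moments(dec: DisequilibriumDecomposition) -> ConditionalMoments:
    """Exact trace-based moments, plus first-order moments of the b ratios."""
    dii = np.diag(dec.D)
    trV = float(dii.sum())
    trV2 = float((dii * dii).sum())
    trW2 = float((dec.W * dec.W).sum())
    trB2 = float((dec.B * dec.B).sum())
    trD2 = float((dec.D * dec.D).sum())
    E_Cw = float(np.trace(dec.W))  # zero: W has a zero diagonal
    E_Cb = float(np.trace(dec.B))
    if trV > 0:
        var_bw = 2.0 * trW2 / trV**2
        var_bb = 2.0 * trB2 / trV**2
        return ConditionalMoments(
            E_Vg=trV, E_Cw=E_Cw, E_Cb=E_Cb, E_VA=trV,
            var_Vg=2.0 * trV2, var_Cw=2.0 * trW2, var_Cb=2.0 * trB2, var_VA=2.0 * trD2,
            E_bw=0.0, E_bb=0.0, E_b=0.0,
            var_bw=var_bw, var_bb=var_bb, var_b=var_bw + var_bb,
            ratios_defined=True,
        )
    return ConditionalMoments(
        E_Vg=trV, E_Cw=E_Cw, E_Cb=E_Cb, E_VA=trV,
        var_Vg=2.0 * trV2, var_Cw=2.0 * trW2, var_Cb=2.0 * trB2, var_VA=2.0 * trD2,
        E_bw=np.nan, E_bb=np.nan, E_b=np.nan,
        var_bw=np.nan, var_bb=np.nan, var_b=np.nan,
        ratios_defined=False,
    )


def b_lower_bound(dec: DisequilibriumDecomposition, guard: float = 1e-9) -> float:
    """Minimum attainable b = a'(W+B)a / a'Va over nonzero effect vectors.

    Computed on the polymorphic subspace as the smallest eigenvalue of
    V^{-1/2} (D - V) V^{-1/2}; positive semidefiniteness of D guarantees the
    value is >= -1 (eigenvalues within ``guard`` below -1 are clipped).
    """
    dii = np.diag(dec.D)
    poly = dii > 0
    if not np.any(poly):
        raise InvalidInputError("no polymorphic loci: the b ratio is undefined")
    idx = np.nonzero(poly)[0]
    s = 1.0 / np.sqrt(dii[idx])
    M = dec.D[np.ix_(idx, idx)] - np.diag(dii[idx])
    M = s[:, None] * M * s[None, :]
    lam = float(scipy.linalg.eigvalsh(M)[0])
    if lam < -1.0 - guard * max(1.0, abs(lam)):
        raise RuntimeError(f"eigenvalue {lam} violates the PSD bound; D is not a valid covariance")
    return max(lam, -1.0)


def _sample_components(
    dec: DisequilibriumDecomposition,
    n_samples: int,
    rng: np.random.Generator,
    sampler=None,
) -> dict:
    L = dec.n_loci
    a = rng.standard_normal((n_samples, L)) if sampler is None else np.asarray(sampler(rng, (n_samples, L)))
    dii = np.diag(dec.D)
    V_g = (a * a) @ dii
    C_w = np.einsum("ij,ij->i", a @ dec.W, a)
    C_b = np.einsum("ij,ij->i", a @ dec.B, a)
    V_A = V_g + C_w + C_b
    defined = V_g > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        b_w = np.where(defined, C_w / V_g, np.nan)
        b_b = np.where(defined, C_b / V_g, np.nan)
    return {
        "V_g": V_g, "C_w": C_w, "C_b": C_b, "C": C_w + C_b, "V_A": V_A,
        "b_w": b_w, "b_b": b_b, "b": b_w + b_b,
    }


def monte_carlo_moments(
    dec: DisequilibriumDecomposition,
    n_samples: int = 10_000,
    seed=None,
    sampler=None,
) -> MonteCarloSummary:
    """Empirical mean/variance/skewness/kurtosis over sampled effect vectors.

    Effects default to i.i.d. standard normal per locus; a custom ``sampler(rng,
    shape)`` may be supplied.  Skewness and kurtosis are the raw standardized
    third and fourth central moments (kurtosis of a normal is 3).
    """
    if n_samples < 100:
        raise InvalidInputError("n_samples must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comps = _sample_components(dec, n_samples, rng, sampler)
    rows = {}
    n_undef = int(np.isnan(comps["b"]).sum())
    for name in COMPONENTS:
        x = comps[name]
        x = x[~np.isnan(x)]
        if x.size == 0:
            rows[name] = dict(mean=np.nan, variance=np.nan, skewness=np.nan, kurtosis=np.nan)
            continue
        rows[name] = dict(
            mean=float(np.mean(x)),
            variance=float(np.var(x)),
            skewness=float(stats.skew(x, bias=True)),
            kurtosis=float(stats.kurtosis(x, fisher=False, bias=True)),
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    return MonteCarloSummary(
        n_samples=n_samples, seed=seed, stats=table, components=comps, n_undefined_ratios=n_undef
    )


def sign_asymmetry_probability(
    dec: DisequilibriumDecomposition, n_samples: int = 10_000, seed=None
) -> SignAsymmetryEstimate:
    """Monte-Carlo estimate of P[C < 0 | X] for a ~ N(0, I).

    Although E[C|X] = 0, the sum of QTL-pair covariances is negative with
    probability above one half whenever coupling-phase disequilibrium spans
    several loci (its distribution is right-skewed).  Reported with the
    binomial standard error; degenerate (no off-diagonal disequilibrium)
    inputs are flagged instead of estimated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.all(dec.W == 0.0) and np.all(dec.B == 0.0):
        return SignAsymmetryEstimate(np.nan, np.nan, n_samples, degenerate=True)
    comps = _sample_components(dec, n_samples, rng)
    frac = float(np.mean(comps["C"] < 0.0))
    se = float(np.sqrt(frac * (1.0 - frac) / n_samples))
    return SignAsymmetryEstimate(frac, se, n_samples, degenerate=False)
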