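"""Scenario orchestration: replicated simulations, aggregated conditional moments,
and the finite-population decay regression for var[b_b].

A scenario is the combination of ancestral panel, mating design, number of
parents P, population size N and number of QTL L.  Each replication samples
parents, produces generations G1..G4 and their DH populations, and draws
fresh QTL sets; the trace-based statistics of every realized genotype matrix
are averaged over all replications x QTL sets, with standard errors taken
across replications.

Under random mating with unlimited population size, between-chromosome GPD
halves every generation, so var[b_b] falls by 1/4 per recombination step r.
With a finite N an extra deviation omega is regenerated each generation:

    vhat_0 = theta + omega,   vhat_{r+1} = vhat_r / 4 + omega
    vhat_r = theta / 4^r + ((4 - 4^{-r}) / 3) omega

with steady state (4/3) omega as r grows.  The model is linear in (theta,
omega), so the fit is an exact least-squares solve (non-negative by default,
with an unconstrained diagnostic refit).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breeding_sim import run_replication
from .founders import FounderSpec, get_preset, sample_qtl, synth_ancestral
from .genotypes import DisequilibriumDecomposition, GenotypeMatrix, InvalidInputError
from .theory import conditional_moments

__all__ = [
    "STATISTICS",
    "Scenario",
    "AggregatedEstimates",
    "DecayFit",
    "run_scenario",
    "decay_curve",
    "report",
    "plot_b_decomposition",
]

STATISTICS = (
    "E_VA", "var_Vg", "var_C", "var_Cw", "var_Cb", "var_VA",
    "var_bw", "var_bb", "var_b",
)


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario; defaults follow the full replication profile
    (500 replications x 50 QTL sets); pass smaller values for desk-scale runs."""

    design: str = "DC"
    P: int = 4
    N: int = 250
    L: int = 250
    n_replications: int = 500
    n_qtl_sets: int = 50
    n_generations: int = 4
    preset: str = "elite-like"
    seed: int = 0

    def __post_init__(self):
        for name in ("P", "N", "L", "n_replications", "n_qtl_sets", "n_generations"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be positive")

    def label(self) -> str:
        return f"{self.preset}_{self.design}_P{self.P}_N{self.N}_L{self.L}"


@dataclass(eq=False)
class AggregatedEstimates:
    """Per-generation averages of the trace statistics over all realizations of X."""

    scenario: Scenario
    estimates: pd.DataFrame        # index: generation label, columns: STATISTICS
    se: pd.DataFrame               # across-replication standard errors
    per_replication: np.ndarray    # (reps, generations, statistics) replication means
    n_realizations: int
    n_undefined: int               # flagged V_g = 0 realizations, excluded from ratio averages
    generations: tuple = ()


def _replication_stats(
    panel: GenotypeMatrix, scenario: Scenario, rng: np.random.Generator
) -> tuple[np.ndarray, int, tuple]:
    """Means over the replication's QTL sets: (generations, statistics) array."""
    gens = run_replication(
        panel, scenario.design, scenario.P, scenario.N,
        n_generations=scenario.n_generations, rng=rng,
    )
    labels = tuple(gens.dh_matrices)
    acc = np.zeros((len(labels), len(STATISTICS)))
    counts = np.zeros((len(labels), len(STATISTICS)))
    undefined = 0
    for _ in range(scenario.n_qtl_sets):
        qtl = sample_qtl(panel.gmap, scenario.L, rng)
        for g, label in enumerate(labels):
            dec = DisequilibriumDecomposition.from_genotypes(gens.dh_matrices[label], qtl.indices)
            m = conditional_moments(dec)
            row = np.array([
                m.E_VA, m.var_Vg, m.var_Cw + m.var_Cb, m.var_Cw, m.var_Cb, m.var_VA,
                m.var_bw, m.var_bb, m.var_b,
            ])
            ok = ~np.isnan(row)
            acc[g, ok] += row[ok]
            counts[g] += ok
            if not m.ratios_defined:
                undefined += 1
    with np.errstate(invalid="ignore"):
        means = acc / counts
    return means, undefined, labels


def run_scenario(
    scenario: Scenario,
    panel: GenotypeMatrix | None = None,
    checkpoint_dir=None,
    progress: bool = False,
) -> AggregatedEstimates:
    """Run all replications of a scenario and aggregate the hat-estimates.

    The master seed spawns one child stream per replication (plus one for the
    synthetic panel when none is supplied), so results are reproducible and a
    checkpointed run resumes to bit-identical aggregates.
    """
    ss = np.random.SeedSequence(scenario.seed)
    panel_ss, *rep_ss = ss.spawn(scenario.n_replications + 1)
    if panel is None:
        spec = get_preset(scenario.preset)
        panel, _ = synth_ancestral(spec, np.random.default_rng(panel_ss))
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)
    per_rep = []
    undefined_total = 0
    labels: tuple = ()
    for r in range(scenario.n_replications):
        path = None if ckpt is None else ckpt / f"rep{r:05d}.npz"
        if path is not None and path.exists():
            with np.load(path, allow_pickle=True) as z:
                means, undefined, labels = z["means"], int(z["undefined"]), tuple(z["labels"])
        else:
            means, undefined, labels = _replication_stats(
                panel, scenario, np.random.default_rng(rep_ss[r])
            )
            if path is not None:
                np.savez(path, means=means, undefined=undefined, labels=np.array(labels, dtype=object))
        per_rep.append(means)
        undefined_total += undefined
        if progress and (r + 1) % 10 == 0:
            print(f"[{scenario.label()}] replication {r + 1}/{scenario.n_replications}", flush=True)
    stack = np.stack(per_rep)  # (reps, gens, stats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if stack.shape[0] > 1 else np.full_like(est, np.nan)
    se = sd / np.sqrt(stack.shape[0])
    return AggregatedEstimates(
        scenario=scenario,
        estimates=pd.DataFrame(est, index=list(labels), columns=list(STATISTICS)),
        se=pd.DataFrame(se, index=list(labels), columns=list(STATISTICS)),
        per_replication=stack,
        n_realizations=scenario.n_replications * scenario.n_qtl_sets,
        n_undefined=undefined_total,
        generations=labels,
    )


@dataclass(frozen=True)
class DecayFit:
    """Least-squares fit of the finite-N decay model for var[b_b]."""

    theta: float
    omega: float
    rss: float
    n_generations: int
    theta_unbounded: float
    omega_unbounded: float
    negative_omega_flag: bool

    @property
    def steady_state(self) -> float:
        """Implied var[b_b] level as r -> infinity: (4/3) omega."""
        return 4.0 * self.omega / 3.0

    def predict(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.theta / 4.0**r + (4.0 - 4.0**-r) / 3.0 * self.omega


def decay_curve(var_bb: np.ndarray) -> DecayFit:
    """Fit theta (infinite-N level at r=0) and omega (finite-N deviation) to a
    series of var[b_b] estimates for recombination steps r = 0, 1, ..., R.

    The first DH generation after the cross (G1-DH) is r = 0.  Both parameters
    are constrained non-negative; an unconstrained diagnostic refit is also
    reported, and a negative unconstrained omega is flagged.
    """
    y = np.asarray(var_bb, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise InvalidInputError("need estimates for at least 3 generations")
    r = np.arange(y.size, dtype=float)
    A = np.column_stack([4.0**-r, (4.0 - 4.0**-r) / 3.0])
    from scipy.optimize import nnls

    coef, _ = nnls(A, y)
    resid = y - A @ coef
    coef_u, *_ = np.linalg.lstsq(A, y, rcond=None)
    return DecayFit(
        theta=float(coef[0]), omega=float(coef[1]), rss=float(resid @ resid),
        n_generations=int(y.size),
        theta_unbounded=float(coef_u[0]), omega_unbounded=float(coef_u[1]),
        negative_omega_flag=bool(coef_u[1] < 0),
    )


def report(
    results: list[AggregatedEstimates],
    outdir,
    fits: dict | None = None,
) -> dict:
    """Write result tables and run metadata.

    ``estimates.csv`` holds one row per scenario x generation x statistic
    (value and across-replication SE); ``metadata.json`` records seeds,
    version and timing.  An empty result list yields a header-only table
    with a warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for agg in results:
        sc = agg.scenario
        for gen in agg.estimates.index:
            for stat in STATISTICS:
                rows.append(
                    dict(
                        preset=sc.preset, design=sc.design, P=sc.P, N=sc.N, L=sc.L,
                        generation=gen, statistic=stat,
                        value=agg.estimates.loc[gen, stat], se=agg.se.loc[gen, stat],
                    )
                )
    columns = ["preset", "design", "P", "N", "L", "generation", "statistic", "value", "se"]
    table = pd.DataFrame(rows, columns=columns)
    if table.empty:
        warnings.warn("no estimates supplied; writing a header-only table", stacklevel=2)
    csv_path = outdir / "estimates.csv"
    table.to_csv(csv_path, index=False)
    meta = {
        "version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "scenarios": [
            dict(label=a.scenario.label(), seed=a.scenario.seed,
                 n_replications=a.scenario.n_replications, n_qtl_sets=a.scenario.n_qtl_sets,
                 n_realizations=a.n_realizations, n_undefined_ratios=a.n_undefined)
            for a in results
        ],
    }
    if fits:
        meta["decay_fits"] = {
            k: dict(theta=f.theta, omega=f.omega, rss=f.rss, steady_state=f.steady_state,
                    omega_unbounded=f.omega_unbounded, negative_omega_flag=f.negative_omega_flag)
            for k, f in fits.items()
        }
    meta_path = outdir / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"estimates": csv_path, "metadata": meta_path}


def plot_b_decomposition(agg: AggregatedEstimates, path) -> None:
    """Stacked bars of hat-var[b_w] and hat-var[b_b] per DH generation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gens = list(agg.estimates.index)
    bw = agg.estimates["var_bw"].to_numpy()
    bb = agg.estimates["var_bb"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(gens, bw, label="var[b_w]", color="#3465a4")
    ax.bar(gens, bb, bottom=bw, label="var[b_b]", color="#cc0000")
    ax.set_ylabel("variance of b")
    ax.set_title(agg.scenario.label())
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
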