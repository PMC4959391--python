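"""Generative O2PLS model and replicate studies of loading recovery.

Data are drawn from the factor model

    X = T W' + T_Yorth P_Yorth' + E,      Y = U C' + U_Xorth P_Xorth' + F,
    U = T B_T + H,

with Gaussian scores and noise.  Loading profiles are normal-density curves
over the variable index — a smooth bump of "important" variables against a
flat background, mimicking e.g. a lipoprotein subgroup in a metabolite panel.
Profiles are normalized to unit Euclidean norm, under which the noise
variances below make the noise fraction exact.

Noise calibration.  Given a target noise level ``alpha`` (the fraction of a
block's expected total sum of squares that is unstructured noise), the noise
variances are

    var_e = alpha/(1-alpha) * (a*var_t + n_x*var_t_orth) / p
    var_h = alpha/(1-alpha) * b_t^2 * var_t
    var_f = alpha/(1-alpha) * (a*(b_t^2*var_t + var_h) + n_y*var_u_orth) / q

so that E[noise SS] / E[total SS] = alpha in each block (var_h feeds into
var_f because H propagates into Y through U).

Two stock designs are provided: a low-dimensional one (N=500, p=100, q=50)
and a higher-dimensional one (p=500, q=250), both with one joint and one
orthogonal component per block, inner slope 2 and unit score variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import PairedData
from .model import fit_o2pls

__all__ = [
    "SimulationDesign",
    "SimulationTruth",
    "SimulationSummary",
    "low_dimensional_design",
    "high_dimensional_design",
    "loading_profile",
    "noise_variances",
    "simulate_dataset",
    "sign_correct",
    "run_study",
]


def loading_profile(
    n_vars: int, mu: float, sigma: float, normalize: bool = True
) -> np.ndarray:
    """Normal-density loading curve over the variable index.

    Entry i (i = 1..n_vars) is the normal density N(i; mu, sigma); with
    ``normalize`` the vector is scaled to unit Euclidean norm.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if sigma <= 0:
        raise ValueError("profile spread sigma must be positive")
    v = stats.norm.pdf(np.arange(1, n_vars + 1), loc=mu, scale=sigma)
    if normalize:
        v = v / np.linalg.norm(v)
    return v


@dataclass
class SimulationDesign:
    """Parameters of the generative model.

    ``w_profiles`` etc. hold one (mu, sigma) pair per component column of
    the corresponding loading factor.  ``b_t`` may be a scalar (single joint
    component) or a sequence giving a diagonal inner-relation matrix.
    """

    N: int = 500
    p: int = 100
    q: int = 50
    a: int = 1
    n_x: int = 1
    n_y: int = 1
    w_profiles: list[tuple[float, float]] = field(default_factory=lambda: [(60, 10)])
    c_profiles: list[tuple[float, float]] = field(default_factory=lambda: [(70, 5)])
    p_yorth_profiles: list[tuple[float, float]] = field(
        default_factory=lambda: [(20, 20)]
    )
    p_xorth_profiles: list[tuple[float, float]] = field(
        default_factory=lambda: [(15, 10)]
    )
    b_t: float | list[float] = 2.0
    var_t: float = 1.0
    var_t_orth: float = 1.0
    var_u_orth: float = 1.0
    alpha: float = 0.05
    normalize_loadings: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        for v in (self.var_t, self.var_t_orth, self.var_u_orth):
            if v <= 0:
                raise ValueError("score variances must be positive")
        if len(self.w_profiles) != self.a or len(self.c_profiles) != self.a:
            raise ValueError("need one (mu, sigma) profile per joint component")
        if len(self.p_yorth_profiles) != self.n_x:
            raise ValueError("need one profile per X-orthogonal component")
        if len(self.p_xorth_profiles) != self.n_y:
            raise ValueError("need one profile per Y-orthogonal component")

    @property
    def b_t_matrix(self) -> np.ndarray:
        b = np.atleast_1d(np.asarray(self.b_t, dtype=float))
        if b.size == 1:
            b = np.full(self.a, b[0])
        if b.size != self.a:
            raise ValueError("b_t must be scalar or have one entry per component")
        return np.diag(b)

    def loadings(self) -> dict[str, np.ndarray]:
        """True loading matrices built from the profiles."""

        def build(n_vars: int, profiles: list[tuple[float, float]]) -> np.ndarray:
            if not profiles:
                return np.zeros((n_vars, 0))
            return np.column_stack(
                [
                    loading_profile(n_vars, mu, sigma, self.normalize_loadings)
                    for mu, sigma in profiles
                ]
            )

        return {
            "W": build(self.p, self.w_profiles),
            "C": build(self.q, self.c_profiles),
            "P_Yorth": build(self.p, self.p_yorth_profiles),
            "P_Xorth": build(self.q, self.p_xorth_profiles),
        }


def low_dimensional_design(alpha: float = 0.05) -> SimulationDesign:
    """Stock design with p=100, q=50 (see module docstring)."""
    return SimulationDesign(alpha=alpha)


def high_dimensional_design(alpha: float = 0.05) -> SimulationDesign:
    """Stock design with p=500, q=250."""
    return SimulationDesign(
        p=500,
        q=250,
        w_profiles=[(300, 50)],
        c_profiles=[(175, 25)],
        p_yorth_profiles=[(100, 100)],
        p_xorth_profiles=[(75, 50)],
        alpha=alpha,
    )


def noise_variances(design: SimulationDesign) -> tuple[float, float, float]:
    """Noise variances (var_e, var_f, var_h) enforcing the noise level alpha.

    See the module docstring for the closed forms.  The mean squared inner
    slope is used when ``b_t`` is a diagonal with distinct entries.
    """
    ratio = design.alpha / (1.0 - design.alpha)
    b_sq = float(np.mean(np.diag(design.b_t_matrix) ** 2))
    var_e = ratio * (design.a * design.var_t + design.n_x * design.var_t_orth) / design.p
    var_h = ratio * b_sq * design.var_t
    var_f = (
        ratio
        * (design.a * (b_sq * design.var_t + var_h) + design.n_y * design.var_u_orth)
        / design.q
    )
    return var_e, var_f, var_h


@dataclass
class SimulationTruth:
    """Generative factors of one simulated dataset, kept for scoring."""

    W: np.ndarray
    C: np.ndarray
    P_Yorth: np.ndarray
    P_Xorth: np.ndarray
    T: np.ndarray
    U: np.ndarray
    T_Yorth: np.ndarray
    U_Xorth: np.ndarray
    H: np.ndarray
    E: np.ndarray
    F: np.ndarray
    B_T: np.ndarray


def simulate_dataset(
    design: SimulationDesign, seed: int
) -> tuple[PairedData, SimulationTruth]:
    """Draw one dataset from the generative model; deterministic given seed."""
    rng = np.random.default_rng(seed)
    L = design.loadings()
    N, a = design.N, design.a
    T = rng.normal(0.0, np.sqrt(design.var_t), size=(N, a))
    T_Yorth = rng.normal(0.0, np.sqrt(design.var_t_orth), size=(N, design.n_x))
    U_Xorth = rng.normal(0.0, np.sqrt(design.var_u_orth), size=(N, design.n_y))
    var_e, var_f, var_h = noise_variances(design)
    H = rng.normal(0.0, np.sqrt(var_h), size=(N, a)) if var_h > 0 else np.zeros((N, a))
    U = T @ design.b_t_matrix + H
    E = (
        rng.normal(0.0, np.sqrt(var_e), size=(N, design.p))
        if var_e > 0
        else np.zeros((N, design.p))
    )
    F = (
        rng.normal(0.0, np.sqrt(var_f), size=(N, design.q))
        if var_f > 0
        else np.zeros((N, design.q))
    )
    X = T @ L["W"].T + T_Yorth @ L["P_Yorth"].T + E
    Y = U @ L["C"].T + U_Xorth @ L["P_Xorth"].T + F
    data = PairedData(
        X=X,
        Y=Y,
        sample_ids=[f"s{i}" for i in range(N)],
        x_var_ids=[f"x{j}" for j in range(design.p)],
        y_var_ids=[f"y{j}" for j in range(design.q)],
    )
    truth = SimulationTruth(
        W=L["W"],
        C=L["C"],
        P_Yorth=L["P_Yorth"],
        P_Xorth=L["P_Xorth"],
        T=T,
        U=U,
        T_Yorth=T_Yorth,
        U_Xorth=U_Xorth,
        H=H,
        E=E,
        F=F,
        B_T=design.b_t_matrix,
    )
    return data, truth


def sign_correct(estimate: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Resolve the sign indeterminacy of estimated loading columns.

    Column j of the output is sign(truth_j' estimate_j) * estimate_j, with
    sign(0) treated as +1, so each estimated column points the same way as
    its true counterpart.
    """
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError(f"shape mismatch: {estimate.shape} vs {truth.shape}")
    signs = np.sign((truth * estimate).sum(axis=0))
    signs[signs == 0] = 1.0
    return estimate * signs


#: loading factors scored in replicate studies
_FACTORS = ("W", "C", "P_Yorth", "P_Xorth")


@dataclass
class SimulationSummary:
    """Across-replicate summaries of sign-corrected loading estimates.

    For each factor: per-entry mean, median, first and third quartiles of
    the estimates, and bias = mean estimate - true loading.
    """

    design: SimulationDesign
    replicates: int
    seeds: list[int]
    truth: dict[str, np.ndarray]
    mean: dict[str, np.ndarray]
    median: dict[str, np.ndarray]
    q1: dict[str, np.ndarray]
    q3: dict[str, np.ndarray]
    bias: dict[str, np.ndarray]
    n_failed: int = 0

    def iqr(self, factor: str) -> np.ndarray:
        """Per-entry interquartile range of the estimates."""
        return self.q3[factor] - self.q1[factor]


def run_study(
    design: SimulationDesign, replicates: int, base_seed: int = 0
) -> SimulationSummary:
    """Replicate loading-recovery study at the design's true components.

    For each replicate r: simulate with seed ``base_seed + r``, center, fit
    at the true (a, n_x, n_y), sign-correct all four loading factors against
    truth, and accumulate.  Replicates whose fit fails are counted and
    skipped.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    estimates: dict[str, list[np.ndarray]] = {f: [] for f in _FACTORS}
    truth_loadings = design.loadings()
    seeds = [base_seed + r for r in range(1, replicates + 1)]
    n_failed = 0
    for seed in seeds:
        data, truth = simulate_dataset(design, seed)
        try:
            model = fit_o2pls(data.center(), design.a, design.n_x, design.n_y)
        except Exception:
            n_failed += 1
            continue
        fitted = {
            "W": model.W,
            "C": model.C,
            "P_Yorth": model.P_Yorth,
            "P_Xorth": model.P_Xorth,
        }
        for f in _FACTORS:
            estimates[f].append(sign_correct(fitted[f], truth_loadings[f]))
    mean, median, q1, q3, bias = {}, {}, {}, {}, {}
    for f in _FACTORS:
        stack = np.stack(estimates[f]) if estimates[f] else np.zeros(
            (0,) + truth_loadings[f].shape
        )
        mean[f] = stack.mean(axis=0)
        median[f] = np.median(stack, axis=0)
        q1[f] = np.quantile(stack, 0.25, axis=0)
        q3[f] = np.quantile(stack, 0.75, axis=0)
        bias[f] = mean[f] - truth_loadings[f]
    return SimulationSummary(
        design=design,
        replicates=replicates,
        seeds=seeds,
        truth=truth_loadings,
        mean=mean,
        median=median,
        q1=q1,
        q3=q3,
        bias=bias,
        n_failed=n_failed,
    )
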