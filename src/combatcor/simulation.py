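"""Synthetic expression data from the hierarchical location/scale batch model.

Datasets are generated gene by gene as

    Y_ijg = alpha_g + X1 beta_g + gamma_ig + delta_ig * eps_ijg,

with a matched batch-free benchmark ``Y_bench = alpha_g + X1 beta_g + eps``
sharing the same background, effects and residual draws.  The stock designs
mirror a five-batch bladder-cancer study: a highly unbalanced layout with
cancer/control counts 11/0, 14/4, 0/4, 0/5, 15/4 per batch (n = 57), and a
balanced counterpart with 6/6, 9/9, 2/2, 3/3, 10/10 (n = 60).

Defaults: 20 000 genes, of which 2 000 are differentially expressed — 500
each at group effects +2, +1, -1, -2 — background level 3, residual
standard deviations sigma_g ~ Gamma(shape 4, rate 10) (mean 0.4), and
per-gene background variation with variance drawn from Gamma(shape 4.5,
rate 1.5).
Batch-effect hyperparameters come in three named levels per moment:

* mean level: gamma_ig ~ N(m_i, v_i) with per-batch (m_i, v_i) from the
  table below; ``"null"`` switches the location effects off entirely;
* variance level: delta_ig ~ InvGamma(shape a_i, scale b_i); ``"null"``
  forces delta = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correction import ExpressionMatrix
from .design import GroupBatchDesign, build_design
from .diffexp import DEResult, run_method

__all__ = [
    "SimScenario",
    "SimDataset",
    "unbalanced_design",
    "balanced_design",
    "stock_hyperparams",
    "simulate_dataset",
    "run_replicates",
    "load_scenario",
]

LEVELS = ("null", "small", "large")

# Per-batch hyperparameters of the batch-effect priors (5 batches).
# m: location-effect means, v: location-effect variances (shared across
# levels), a/b: inverse-gamma shape/scale of the scale effects.
_MEAN_M = {
    "small": (-0.04, 0.15, -0.15, -0.10, -0.08),
    "large": (-0.40, 1.50, -1.50, 1.00, -0.80),
}
_MEAN_V = (0.15, 0.35, 0.82, 0.46, 0.12)
_VAR_A = {
    "small": (60.0, 100.0, 56.0, 30.0, 100.0),
    "large": (100.0, 120.0, 100.0, 60.0, 40.0),
}
_VAR_B = {
    "small": (60.0, 100.0, 50.0, 30.0, 100.0),
    "large": (100.0, 40.0, 60.0, 100.0, 120.0),
}

#: cancer/control counts per batch for the stock designs
UNBALANCED_LAYOUT = ((11, 0), (14, 4), (0, 4), (0, 5), (15, 4))
BALANCED_LAYOUT = ((6, 6), (9, 9), (2, 2), (3, 3), (10, 10))


def _layout_design(layout) -> GroupBatchDesign:
    groups, batches = [], []
    for i, (n_case, n_ctrl) in enumerate(layout, start=1):
        groups += ["control"] * n_ctrl + ["cancer"] * n_case
        batches += [f"batch{i}"] * (n_ctrl + n_case)
    return build_design(groups, batches)


def unbalanced_design() -> GroupBatchDesign:
    """Five-batch unbalanced layout (11/0, 14/4, 0/4, 0/5, 15/4), n = 57."""
    return _layout_design(UNBALANCED_LAYOUT)


def balanced_design() -> GroupBatchDesign:
    """Five-batch balanced layout (6/6, 9/9, 2/2, 3/3, 10/10), n = 60."""
    return _layout_design(BALANCED_LAYOUT)


def stock_hyperparams(mean_level: str, var_level: str):
    """Per-batch (m_i, v_i, a_i, b_i) for the named batch-effect levels.

    Returns a dict of length-5 arrays ``m``, ``v``, ``a``, ``b`` plus the
    boolean flags ``gamma_off`` / ``delta_off`` encoding the null levels.
    """
    for lev in (mean_level, var_level):
        if lev not in LEVELS:
            raise ValueError(f"level {lev!r} not in {LEVELS}")
    gamma_off = mean_level == "null"
    delta_off = var_level == "null"
    m = np.zeros(5) if gamma_off else np.asarray(_MEAN_M[mean_level])
    v = np.zeros(5) if gamma_off else np.asarray(_MEAN_V)
    a = np.full(5, np.nan) if delta_off else np.asarray(_VAR_A[var_level])
    b = np.full(5, np.nan) if delta_off else np.asarray(_VAR_B[var_level])
    return {"m": m, "v": v, "a": a, "b": b, "gamma_off": gamma_off, "delta_off": delta_off}


DEFAULT_DE_SPEC = ((2.0, 500), (1.0, 500), (-1.0, 500), (-2.0, 500))


@dataclass
class SimScenario:
    """One simulation condition: a design plus batch-effect levels."""

    design: GroupBatchDesign
    mean_level: str = "small"
    var_level: str = "small"
    n_genes: int = 20_000
    #: (effect, count) pairs; None scales the default 500-per-effect layout
    #: proportionally to n_genes (10% DE overall)
    de_spec: tuple | None = DEFAULT_DE_SPEC
    background: float = 3.0
    sigma_shape: float = 4.0
    sigma_rate: float = 10.0
    gene_var_shape: float = 4.5
    gene_var_rate: float = 1.5
    seed: int = 0
    #: custom per-batch hyperparameters (same keys as stock_hyperparams);
    #: required for designs whose batch count differs from 5
    hyperparams: dict | None = None

    def resolved_de_spec(self) -> tuple:
        if self.de_spec is not None:
            return tuple(self.de_spec)
        scale = self.n_genes / 20_000
        return tuple((e, max(1, round(c * scale))) for e, c in DEFAULT_DE_SPEC)

    def resolved_hyperparams(self) -> dict:
        if self.hyperparams is not None:
            return self.hyperparams
        if self.design.n_batches != 5:
            raise ValueError(
                "stock hyperparameters cover 5 batches; supply `hyperparams` "
                f"for a design with {self.design.n_batches}"
            )
        return stock_hyperparams(self.mean_level, self.var_level)


@dataclass
class SimDataset:
    """A simulated matrix, its batch-free benchmark and the ground truth."""

    Y: ExpressionMatrix
    Y_bench: ExpressionMatrix
    truth: np.ndarray        # per-gene true group effect (0 for null genes)
    gamma: np.ndarray        # (G, B) drawn location effects
    delta: np.ndarray        # (G, B) drawn scale effects
    sigma2: np.ndarray       # (G,) residual variances
    scenario: SimScenario = field(repr=False, default=None)

    @property
    def is_de(self) -> np.ndarray:
        return self.truth != 0


def simulate_dataset(s: SimScenario, seed: int | None = None) -> SimDataset:
    """Draw one dataset (and its benchmark) from the scenario, reproducibly."""
    rng = np.random.default_rng(s.seed if seed is None else seed)
    d = s.design
    G, n, B = s.n_genes, d.n, d.n_batches
    hp = s.resolved_hyperparams()

    de_spec = s.resolved_de_spec()
    n_de = sum(c for _, c in de_spec)
    if n_de > G:
        raise ValueError(f"{n_de} DE genes requested but only {G} genes simulated")
    truth = np.zeros(G)
    pos = rng.permutation(G)
    start = 0
    for effect, count in de_spec:
        truth[pos[start:start + count]] = effect
        start += count

    # per-gene background: level 3 plus variation with gamma-distributed variance
    tau2 = rng.gamma(shape=s.gene_var_shape, scale=1.0 / s.gene_var_rate, size=G)
    alpha_g = s.background + rng.normal(0.0, np.sqrt(tau2))
    # residual SDs are gamma draws (mean 0.4, so E[sigma^2] ~ 0.2)
    sigma = rng.gamma(shape=s.sigma_shape, scale=1.0 / s.sigma_rate, size=G)
    sigma2 = sigma**2
    eps = rng.normal(0.0, 1.0, size=(G, n)) * sigma[:, None]

    if hp["gamma_off"]:
        gamma = np.zeros((G, B))
    else:
        gamma = rng.normal(hp["m"], np.sqrt(hp["v"]), size=(G, B))
    if hp["delta_off"]:
        delta = np.ones((G, B))
    else:
        # InvGamma(shape a, scale b) == b / Gamma(shape a, scale 1)
        delta = hp["b"] / rng.gamma(shape=np.broadcast_to(hp["a"], (G, B)), scale=1.0)

    x = d.X1[:, 1]  # 0/1 group indicator
    mean_surface = alpha_g[:, None] + np.outer(truth, x)
    bench = mean_surface + eps

    onehot = d.batch_onehot
    gamma_s = gamma @ onehot.T
    delta_s = delta @ onehot.T
    Y = mean_surface + gamma_s + delta_s * eps

    gene_ids = [f"gene{i + 1}" for i in range(G)]
    return SimDataset(
        Y=ExpressionMatrix(Y, gene_ids, list(d.sample_ids)),
        Y_bench=ExpressionMatrix(bench, gene_ids, list(d.sample_ids)),
        truth=truth,
        gamma=gamma,
        delta=delta,
        sigma2=sigma2,
        scenario=s,
    )


def load_scenario(path) -> SimScenario:
    """Build a scenario from a YAML/JSON config file.

    Recognised keys: ``design`` ("unbalanced" | "balanced"), ``mean_level``,
    ``var_level``, ``n_genes``, ``de_spec`` (list of [effect, count] pairs),
    ``seed``.  Unknown keys are rejected.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    allowed = {"design", "mean_level", "var_level", "n_genes", "de_spec", "seed"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
    name = cfg.pop("design", "unbalanced")
    if name == "unbalanced":
        design = unbalanced_design()
    elif name == "balanced":
        design = balanced_design()
    else:
        raise ValueError(f"unknown design {name!r} (choose unbalanced or balanced)")
    if "de_spec" in cfg and cfg["de_spec"] is not None:
        cfg["de_spec"] = tuple((float(e), int(c)) for e, c in cfg["de_spec"])
    for key in ("mean_level", "var_level"):
        # a bare `null` in YAML parses to None; treat it as the null level
        if cfg.get(key, "") is None:
            cfg[key] = "null"
    return SimScenario(design=design, **cfg)


def replicate_seeds(seed: int, n_reps: int) -> list[int]:
    """Child seeds for replicate r: drawn from SeedSequence(seed).spawn."""
    return [int(ss.generate_state(1)[0] % (2**31)) for ss in np.random.SeedSequence(seed).spawn(n_reps)]


def run_replicates(
    s: SimScenario,
    n_reps: int,
    methods: tuple[str, ...],
    zeta: float | None = None,
) -> list[tuple[SimDataset, dict[str, DEResult]]]:
    """Simulate ``n_reps`` replicate datasets and analyse each with ``methods``.

    Replicate seeds are spawned from the scenario seed, so the stream is
    reproducible and replicates are mutually independent.
    """
    out = []
    for child in replicate_seeds(s.seed, n_reps):
        sim = simulate_dataset(s, seed=child)
        results = {
            tag: run_method(tag, sim.Y, s.design, Y_bench=sim.Y_bench, zeta=zeta)
            for tag in methods
        }
        out.append((sim, results))
    return out
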