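"""Synthetic cohorts with known EMT ground truth.

Every downstream stage of the package (projection, scoring, segmentation,
genomic association) can be exercised end-to-end on data generated here,
with the latent EMT position, macro-state, purity and planted genomic
events all known.

The generative model places each cell or tumour on a latent EMT axis
t in [0, 100].  Epithelial markers follow a decreasing sigmoid of t,
mesenchymal markers an increasing sigmoid, and hybrid markers a Gaussian
bump centred at t = 50; non-marker genes are t-independent.  Bulk samples
are purity-weighted mixtures of the tumour profile at their latent t and
a fixed fibroblast-like stromal profile, plus gene-wise batch offsets.
Values are Gaussian on the log scale: dropout and library-size effects of
real scRNA-seq counts are deliberately not modelled, because the
projection contract operates on log-normalised expression.

All generators are pure functions of (config, seed): the same
``SimulationConfig`` always yields the same draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ReferenceTrajectory
from .markers import DEFAULT_MARKERS

# Response-curve constants. Baseline and amplitude are on the log-expression
# scale; slopes/midpoints are drawn per gene so markers are informative but
# not collinear. Chosen so the three terciles of t separate at noise_sd ~ 0.3.
_BASE_LO = 2.0
_AMPLITUDE = 3.0
_MID_RANGE = (40.0, 60.0)
_SLOPE_RANGE = (0.10, 0.20)
_BUMP_CENTRE = 50.0
_BUMP_WIDTH_RANGE = (10.0, 18.0)

_MIN_GENES = 32  # the curated marker panel must fit

TERCILE_EDGES = (100.0 / 3.0, 200.0 / 3.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohorts."""

    n_cells: int = 500
    n_bulk: int = 300
    n_genes: int = 200
    noise_sd: float = 0.3
    batch_shift: float = 0.5
    purity_range: tuple[float, float] = (0.6, 1.0)
    n_tissues: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_bulk, self.n_genes, self.n_tissues) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_genes < _MIN_GENES:
            raise ValueError(
                f"n_genes must be >= {_MIN_GENES} so the curated marker panel fits"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("purity_range must be ordered and within [0, 1]")


@dataclass
class GroundTruth:
    """Latent values planted by the simulators."""

    true_pseudotime: np.ndarray
    true_state: np.ndarray
    true_purity: np.ndarray
    planted_events: list = field(default_factory=list)


def states_from_pseudotime(t: np.ndarray) -> np.ndarray:
    """Tercile rule for ground-truth macro-states: EPI / hEMT / MES."""
    t = np.asarray(t, float)
    out = np.where(t < TERCILE_EDGES[0], "EPI",
                   np.where(t < TERCILE_EDGES[1], "hEMT", "MES"))
    return out.astype(object)


# ---------------------------------------------------------------------------
# gene panel


@dataclass
class _GenePanel:
    genes: pd.Index
    kind: np.ndarray          # 'epi' | 'mes' | 'hyb' | 'none'
    mid: np.ndarray
    slope: np.ndarray
    width: np.ndarray
    base: np.ndarray          # constant level for non-marker genes
    stromal_offset: np.ndarray

    def tumour_profile(self, t: np.ndarray) -> np.ndarray:
        """Noise-free expression (genes x len(t)) at latent positions t."""
        t = np.atleast_1d(np.asarray(t, float))
        out = np.empty((len(self.genes), t.size))
        sig = 1.0 / (1.0 + np.exp(-self.slope[:, None] * (t[None, :] - self.mid[:, None])))
        bump = np.exp(-((t[None, :] - _BUMP_CENTRE) ** 2) / (2 * self.width[:, None] ** 2))
        out[:] = self.base[:, None]
        epi, mes, hyb = (self.kind == k for k in ("epi", "mes", "hyb"))
        out[epi] = _BASE_LO + _AMPLITUDE * (1.0 - sig[epi])
        out[mes] = _BASE_LO + _AMPLITUDE * sig[mes]
        out[hyb] = _BASE_LO + _AMPLITUDE * bump[hyb]
        return out

    def stromal_profile(self) -> np.ndarray:
        """Fixed fibroblast-like contaminant profile.

        Fibroblasts express intermediate filaments and ECM genes well
        above carcinoma cells even at the mesenchymal end of the
        trajectory, and epithelial adhesion genes not at all, so the
        stromal profile sits beyond the tumour MES extreme on the marker
        axes.
        """
        out = self.base + self.stromal_offset
        out[self.kind == "epi"] = _BASE_LO
        out[self.kind == "mes"] = _BASE_LO + 1.5 * _AMPLITUDE
        out[self.kind == "hyb"] = _BASE_LO + 0.8 * _AMPLITUDE
        return out


def _gene_panel(cfg: SimulationConfig) -> _GenePanel:
    # Panel parameters depend only on cfg.seed, so a reference and a bulk
    # cohort built from the same config share identical response curves.
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    m = DEFAULT_MARKERS
    names = list(m.epithelial) + list(m.mesenchymal) + list(m.hybrid)
    names += [f"GENE{i:04d}" for i in range(1, cfg.n_genes - len(names) + 1)]
    kind = np.array(
        ["epi"] * len(m.epithelial)
        + ["mes"] * len(m.mesenchymal)
        + ["hyb"] * len(m.hybrid)
        + ["none"] * (cfg.n_genes - _MIN_GENES),
        dtype=object,
    )
    n = cfg.n_genes
    return _GenePanel(
        genes=pd.Index(names),
        kind=kind,
        mid=rng.uniform(*_MID_RANGE, n),
        slope=rng.uniform(*_SLOPE_RANGE, n),
        width=rng.uniform(*_BUMP_WIDTH_RANGE, n),
        base=rng.uniform(2.0, 8.0, n),
        stromal_offset=rng.normal(0.0, 0.5, n),
    )


# ---------------------------------------------------------------------------
# generators


def simulate_reference(cfg: SimulationConfig) -> tuple[ReferenceTrajectory, GroundTruth]:
    """Draw a single-cell reference trajectory along the latent EMT axis."""
    panel = _gene_panel(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    t = rng.uniform(0.0, 100.0, cfg.n_cells)
    values = panel.tumour_profile(t) + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, cfg.n_cells))
    cells = pd.Index([f"CELL{i:05d}" for i in range(1, cfg.n_cells + 1)])
    expr = ExpressionMatrix(values, panel.genes, cells)
    ref = ReferenceTrajectory(expr, t, name=f"synthref-s{cfg.seed}")
    truth = GroundTruth(t, states_from_pseudotime(t), np.ones(cfg.n_cells))
    return ref, truth


def simulate_bulk_cohort(
    cfg: SimulationConfig, ref: ReferenceTrajectory
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw bulk tumours as purity-weighted tumour/stroma mixtures.

    Each sample sits at a latent t; its profile is
    ``purity * tumour(t) + (1 - purity) * stroma + batch_offset + noise``
    with gene-wise batch offsets of standard deviation ``cfg.batch_shift``
    (the platform shift the batch-correction stage must remove).
    """
    panel = _gene_panel(cfg)
    if set(ref.expression.gene_ids) != set(panel.genes):
        raise ValueError("reference gene space does not match the config's gene panel")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    t = rng.uniform(0.0, 100.0, cfg.n_bulk)
    purity = rng.uniform(cfg.purity_range[0], cfg.purity_range[1], cfg.n_bulk)
    offsets = (
        rng.normal(0.0, cfg.batch_shift, cfg.n_genes)
        if cfg.batch_shift > 0
        else np.zeros(cfg.n_genes)
    )
    tumour = panel.tumour_profile(t)
    stroma = panel.stromal_profile()
    values = (
        purity[None, :] * tumour
        + (1.0 - purity[None, :]) * stroma[:, None]
        + offsets[:, None]
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, cfg.n_bulk))
    )
    samples = pd.Index([f"BULK{i:05d}" for i in range(1, cfg.n_bulk + 1)])
    tissue = np.array(
        [f"T{(i % cfg.n_tissues) + 1}" for i in range(cfg.n_bulk)], dtype=object
    )
    expr = ExpressionMatrix(
        values, panel.genes, samples,
        batch=np.array(["bulk"] * cfg.n_bulk, dtype=object),
        tissue=tissue, purity=purity,
    )
    return expr, GroundTruth(t, states_from_pseudotime(t), purity)


def simulate_timecourse(
    cfg: SimulationConfig,
    time_points: Sequence[float],
    mus: Optional[Sequence[float]] = None,
    sigma: float = 5.0,
    n_replicates: int = 3,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Emulate an EMT-induction time course (e.g. TGF-beta treatment).

    Samples at time point ``time_points[j]`` draw their latent position
    from Normal(mus[j], sigma), clipped to [0, 100]; ``mus`` defaults to a
    linear ramp from 10 to 90.  Pure tumour profiles, no stromal mixing.
    """
    tp = np.asarray(list(time_points), float)
    if tp.size == 0 or np.any(np.diff(tp) <= 0):
        raise ValueError("time_points must be strictly increasing")
    if mus is None:
        mus = np.linspace(10.0, 90.0, tp.size)
    mus = np.asarray(list(mus), float)
    if mus.shape != tp.shape:
        raise ValueError("mus must have one value per time point")
    panel = _gene_panel(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    t, names = [], []
    for j, (tpj, mu) in enumerate(zip(tp, mus)):
        draw = mu + sigma * rng.standard_normal(n_replicates) if sigma > 0 else np.full(n_replicates, mu)
        t.append(np.clip(draw, 0.0, 100.0))
        names += [f"TP{j + 1:02d}_R{r + 1:02d}" for r in range(n_replicates)]
    t = np.concatenate(t)
    values = panel.tumour_profile(t) + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, t.size))
    expr = ExpressionMatrix(values, panel.genes, pd.Index(names))
    return expr, GroundTruth(t, states_from_pseudotime(t), np.ones(t.size))


def simulate_genomic_events(
    cfg: SimulationConfig,
    truth: GroundTruth,
    n_events: int = 100,
    n_planted: int = 5,
    effect_size: float = 10.0,
    baseline_rate: float = 0.10,
    n_confounded: int = 0,
    planted_states: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Plant binary genomic events with state-dependent frequencies.

    Planted events keep the baseline odds outside their associated state
    and have those odds multiplied by ``effect_size`` inside it.  A further
    ``n_confounded`` background events vary in frequency by tissue only —
    decoys the tissue-adjusted association model should reject.
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if n_planted > n_events:
        raise ValueError("n_planted cannot exceed n_events")
    if n_planted + n_confounded > n_events:
        raise ValueError("planted + confounded events exceed n_events")
    states = np.asarray(truth.true_state, dtype=object)
    n = states.size
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    tissues = np.array([f"T{(i % cfg.n_tissues) + 1}" for i in range(n)], dtype=object)

    if planted_states is None:
        cycle = ("EPI", "hEMT", "MES")
        planted_states = [cycle[i % 3] for i in range(n_planted)]
    planted_states = list(planted_states)
    if len(planted_states) != n_planted:
        raise ValueError("planted_states must have one state per planted event")

    odds = baseline_rate / (1.0 - baseline_rate)
    p_assoc = (odds * effect_size) / (1.0 + odds * effect_size)

    event_ids = [f"EV{i:04d}" for i in range(1, n_events + 1)]
    mat = np.zeros((n, n_events), dtype=np.int8)
    planted: list[tuple[str, str, float]] = []
    for j in range(n_events):
        p = np.full(n, baseline_rate)
        if j < n_planted:
            st = planted_states[j]
            p[states == st] = p_assoc
            planted.append((event_ids[j], st, effect_size))
        elif j < n_planted + n_confounded:
            per_tissue = {tl: rng.uniform(0.02, 0.35) for tl in np.unique(tissues)}
            p = np.array([per_tissue[tl] for tl in tissues])
        mat[:, j] = rng.random(n) < p
    sample_ids = [f"BULK{i:05d}" for i in range(1, n + 1)]
    df = pd.DataFrame(mat, index=pd.Index(sample_ids, name="sample_id"), columns=event_ids)
    return df, planted
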