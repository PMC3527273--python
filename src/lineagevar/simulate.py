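"""Stochastic positive-feedback lineage simulator.

Generates micro-colony tracking data from a single founder under the
minimal model of sub-inhibitory antibiotic stress:

* **Drug uptake with permeability feedback.**  Intracellular drug follows
  ``dD/dt = u0·(1 + β·S)·D_out − k·D``: damage makes the membrane leakier
  (the positive feedback loop), and the pool is diluted by growth.
* **Damage.**  ``dS/dt = σ_s·D·k − k·S``: damage is produced by
  mistranslation, proportional to drug level times translational activity
  (∝ growth), and diluted by growth.  At growth arrest S freezes — damage
  is heritable state.
* **Reporter expression.**  ``dF/dt = α0 + α1·S^h/(K^h + S^h) − k·F`` plus
  multiplicative noise ``η·√F·ξ(t)``; F is the stress-reporter
  concentration.
* **Growth inhibition.**  ``k = k_max / (1 + (S/K_g)^m)`` with
  ``k_max = ln2/T_d``; length grows as ``dL/dt = k·L`` and the cell divides
  on doubling its birth length.
* **Division.**  Volume splits with a stochastic fraction q; molecule
  contents (drug, damage, reporter) are partitioned binomially with
  probability q, conserving integer molecule numbers exactly.
* **Death.**  A growth rate below ``death_rate_floor`` sustained for
  ``arrest_duration`` marks the cell growth-arrested; it stays in the
  colony (and in every census) but never divides again.
* **Co-reporter** (optional).  A passive transcriptional inducer enters
  through the same membrane: ``dF2/dt = u0·(1+β·S)·A_out − k·F2``.  Under
  stress with β > 0 it co-varies with the stress reporter; with β = 0 it
  does not — the in-silico membrane-permeability readout.

Defaults describe the unstressed (null) condition: no drug, no feedback,
constant stochastic production — the regime whose lineage autocorrelation
half-life is one doubling time.  The named presets switch on the stressed
regime; their values are calibrated so the simulator reproduces the
qualitative stressed phenomenology (bimodal growth rates with a dead
sub-population, SLCV rising above IDCV after induction, autocorrelation
half-life of several generations), not fitted to any measured data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError, FitError, SimulationError
from .lineage import CellRecord, LineageTree, SampleTable

__all__ = [
    "SimParams", "CellState", "PRESETS", "get_params", "step_cell",
    "divide_cell", "simulate_tree", "simulate_forest", "fit_moments",
    "growth_rate_from_stress",
]

LN2 = math.log(2.0)


@dataclass
class SimParams:
    """Full parameter set of the stochastic lineage model.

    Units: times in minutes, rates in min⁻¹, lengths in µm, concentrations
    in arbitrary units (a.u.); ``molecule_scale`` converts a.u.·µm of
    content into integer molecules for partitioning.
    """

    doubling_time: float = 23.0          # T_d, minutes
    frame_interval: float = 1.5          # minutes between frames
    n_generations_pre_stress: int = 4    # informational; induction is by size
    induction_colony_size: int = 8       # cells at which drug is switched on
    drug_outside: float = 0.0            # D_out, a.u. (0 = unstressed)
    inducer_outside: float = 0.0         # A_out, a.u. (co-reporter inducer)
    uptake_base: float = 0.02            # u0, min⁻¹ (slow membrane passage)
    drug_efflux: float = 0.02            # passive back-diffusion, min⁻¹
    feedback_gain: float = 0.0           # β, permeability increase per damage
    stress_gain: float = 0.6             # σ_s, damage per drug per unit growth
    basal_damage: float = 0.0            # σ0, drug-free misfolded-protein load
    expression_basal: float = 3.0        # α0, a.u.·min⁻¹
    expression_induced: float = 30.0     # α1, a.u.·min⁻¹ at full induction
    induction_K: float = 0.5             # Hill K of expression on damage
    induction_hill: float = 2.0          # Hill h
    growth_inhibition_K: float = 1.3     # K_g, damage for half-maximal growth
    growth_hill: float = 8.0             # m
    expression_noise: float = 0.5        # η, noise amplitude
    damage_noise: float = 0.0            # η_s, burstiness of damage production
    noise_mode: str = "multiplicative"   # 'multiplicative' (√F) or 'additive'
    partition_asymmetry: float = 0.1     # cv_div; q ~ N(0.5, cv_div/2)
    damage_partition_cv: float = 0.1     # damage segregates with its own q
    div_size_cv: float = 0.05            # lognormal jitter on division size
    molecule_scale: float = 6.0          # molecules per a.u.·µm
    death_rate_floor: float = 0.006      # k_death, min⁻¹
    arrest_duration: float = 60.0        # τ_arrest, minutes
    vigor_cv: float = 0.0                # heritable growth/expression capacity
    vigor_inheritance: float = 0.6       # log-AR(1) coefficient per division
    birth_length: float = 1.75           # founder birth length, µm
    px_per_um: float = 10.0              # centroid coordinate scale
    max_colony_size: int = 200
    t_max: float = 400.0
    n_substeps: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.doubling_time <= 0:
            raise DomainError("doubling_time must be > 0")
        if not 0.0 <= self.partition_asymmetry < 1.0:
            raise DomainError("partition_asymmetry must be in [0, 1)")
        for name in ("frame_interval", "uptake_base", "feedback_gain",
                     "stress_gain", "basal_damage",
                     "expression_basal", "expression_induced",
                     "expression_noise", "drug_outside", "inducer_outside",
                     "molecule_scale", "death_rate_floor", "arrest_duration"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def k_max(self) -> float:
        return LN2 / self.doubling_time


# Calibrated presets (see docs/methods.md for the calibration rationale).
_STRESSED = dict(
    drug_outside=1.0, feedback_gain=4.5, stress_gain=0.55, basal_damage=0.2,
    damage_noise=0.03, damage_partition_cv=0.35, induction_K=1.0,
    expression_induced=45.0, expression_noise=0.35,
    max_colony_size=600, t_max=500.0,
)
PRESETS: dict[str, dict] = {
    "null": {},
    "stressed": dict(_STRESSED),
    "stressed_coreporter": dict(_STRESSED, inducer_outside=1.0),
    "stressed_coreporter_nofeedback": dict(
        _STRESSED, inducer_outside=1.0, feedback_gain=0.0),
    "unstressed_heterogeneous": dict(vigor_cv=0.15),
}


def get_params(preset: str = "null", **overrides) -> SimParams:
    """A :class:`SimParams` from a named preset plus keyword overrides."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    p = SimParams(**PRESETS[preset])
    p = replace(p, **overrides)
    p.validate()
    return p


@dataclass
class CellState:
    """Intensive state of one cell (or, elementwise, of many cells)."""

    length: float | np.ndarray          # µm
    D_in: float | np.ndarray = 0.0      # intracellular drug, a.u.
    S: float | np.ndarray = 0.0         # damage, a.u.
    F: float | np.ndarray = 0.0         # stress reporter, a.u.
    F2: float | np.ndarray = 0.0        # co-reporter, a.u.


def growth_rate_from_stress(S, params: SimParams, vigor=1.0):
    """Instantaneous growth rate k = vigor·k_max / (1 + (S/K_g)^m)."""
    return vigor * params.k_max / (
        1.0 + (np.asarray(S, dtype=float) / params.growth_inhibition_K)
        ** params.growth_hill)


def _hill(S, K, h):
    Sh = np.asarray(S, dtype=float) ** h
    return Sh / (K ** h + Sh)


def step_cell(
    state: CellState,
    params: SimParams,
    dt: float,
    d_out: float = 0.0,
    rng: np.random.Generator | None = None,
    vigor=1.0,
    clamp_counter: list | None = None,
) -> CellState:
    """One stochastic integration step of the single-cell dynamics.

    The drift, linear once the rates are frozen at the step start, is
    integrated exactly over the substep (exponential integrator); the
    diffusion terms are added Euler–Maruyama style.  Works elementwise on
    array-valued states, which is how the colony simulation advances all
    cells at once.  ``d_out`` is the current extracellular drug level;
    noise is drawn from ``rng`` (omit it, or set the noise amplitudes to
    zero, for the deterministic skeleton).  Length integrates exactly as
    exp(k·dt) so noise-free growth is exactly exponential.
    """
    if dt > params.frame_interval + 1e-12:
        raise DomainError("dt must not exceed the frame interval")
    k = growth_rate_from_stress(state.S, params, vigor)
    uptake = params.uptake_base * (1.0 + params.feedback_gain * state.S)
    # linear drift integrated exactly over the substep with rates frozen at
    # the step start (exponential integrator); noise added Euler-Maruyama
    lam_d = params.drug_efflux + k
    w_d = -np.expm1(-lam_d * dt) / lam_d        # -> dt as lam_d -> 0
    D_new = state.D_in * np.exp(-lam_d * dt) + uptake * d_out * w_d
    w_k = -np.expm1(-k * dt) / k
    decay = np.exp(-k * dt)
    # trapezoidal forcing: damage production sees the mean drug level over
    # the substep, which matters during the fast uptake transient
    d_mid = 0.5 * (state.D_in + D_new)
    S_prod = (params.stress_gain * d_mid + params.basal_damage) * k
    S_new = state.S * decay + S_prod * w_k
    if rng is not None and params.damage_noise > 0:
        # bursty damage production (random membrane-damage events)
        S_new = S_new + params.damage_noise * np.sqrt(
            np.maximum(state.S, 0.0) * dt) * rng.standard_normal(
                np.shape(state.S))
    prod = (params.expression_basal
            + params.expression_induced
            * _hill(state.S, params.induction_K, params.induction_hill))
    prod = prod * np.asarray(vigor, dtype=float) ** 2
    F_new = state.F * decay + prod * w_k
    if rng is not None and params.expression_noise > 0:
        xi = rng.standard_normal(np.shape(state.F))
        if params.noise_mode == "multiplicative":
            F_new = F_new + params.expression_noise * np.sqrt(
                np.maximum(state.F, 0.0) * dt) * xi
        else:
            F_new = F_new + params.expression_noise * math.sqrt(dt) * xi
    F2_new = state.F2 * decay + uptake * params.inducer_outside * w_k
    L_new = state.length * np.exp(k * dt)

    def _clamp(v):
        neg = np.asarray(v) < 0
        if np.any(neg):
            if clamp_counter is not None:
                clamp_counter.append(int(np.sum(neg)))
            v = np.maximum(v, 0.0)
        return v

    return CellState(L_new, _clamp(D_new), _clamp(S_new),
                     _clamp(F_new), _clamp(F2_new))


def _draw_q(cv: float, rng: np.random.Generator | None,
            lo: float = 0.2, hi: float = 0.8) -> float:
    if rng is None or cv == 0:
        return 0.5
    while True:
        q = rng.normal(0.5, cv / 2.0)
        if lo < q < hi:
            return float(q)


def divide_cell(
    state: CellState, params: SimParams, rng: np.random.Generator | None = None
) -> tuple[CellState, CellState]:
    """Split one cell into two daughters, conserving molecule contents.

    Volume splits with fraction ``q`` (truncated normal around 1/2); each
    species' content (concentration × length × molecule_scale, rounded to
    integer molecules) is partitioned Binomial(n, q), and daughter
    concentrations are recomputed from their share.  Damage uses its own
    split probability drawn with ``damage_partition_cv`` — aggregated,
    misfolded material segregates far more asymmetrically than volume does.
    Without an ``rng`` the split is deterministic: q = 1/2 and contents
    halve (odd counts leave the extra molecule with the first daughter).
    """
    q = _draw_q(params.partition_asymmetry, rng)
    q_damage = _draw_q(params.damage_partition_cv, rng, lo=0.05, hi=0.95)
    L = float(state.length)
    L1, L2 = q * L, (1.0 - q) * L
    concs = {}
    for name in ("D_in", "S", "F", "F2"):
        c = float(getattr(state, name))
        n = int(round(c * L * params.molecule_scale))
        qx = q_damage if name == "S" else q
        if rng is None:
            n1 = n - n // 2          # deterministic halving
        else:
            n1 = int(rng.binomial(n, qx))
        concs[name] = (n1 / (L1 * params.molecule_scale),
                       (n - n1) / (L2 * params.molecule_scale))
    d1 = CellState(L1, concs["D_in"][0], concs["S"][0],
                   concs["F"][0], concs["F2"][0])
    d2 = CellState(L2, concs["D_in"][1], concs["S"][1],
                   concs["F"][1], concs["F2"][1])
    return d1, d2


# ---------------------------------------------------------------------------
# Whole-colony simulation
# ---------------------------------------------------------------------------

class _Roster:
    """Growing structure-of-arrays over the currently alive cells."""

    FIELDS = ("length", "D_in", "S", "F", "F2", "vigor", "birth_len",
              "div_target", "arrest_min")

    def __init__(self):
        for f in self.FIELDS:
            setattr(self, f, np.empty(0))
        self.arrested = np.empty(0, dtype=bool)
        self.rec_idx: list[int] = []       # index into the record list


def simulate_tree(
    params: SimParams, seed: int | np.random.Generator | None = None
) -> LineageTree:
    """Grow a micro-colony from one founder and emit its tracking tree.

    The extracellular drug (and co-reporter inducer) is switched on at the
    frame where the colony first counts ``induction_colony_size`` cells,
    provided the preset defines a non-zero outside concentration.  The run
    stops when the colony reaches ``max_colony_size`` cells or ``t_max``
    minutes; all surviving cells are then censored (or marked arrested).
    Identical seeds give bit-identical trees.
    """
    params.validate()
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    dt = params.frame_interval / params.n_substeps
    f_eq = params.expression_basal / params.k_max   # unstressed F fixed point

    records: list[dict] = []

    def new_record(parent_i: int | None, birth_t: float, x: float, y: float):
        i = len(records)
        records.append(dict(
            cell_id=f"c{i + 1:05d}",
            parent_id=None if parent_i is None else records[parent_i]["cell_id"],
            birth=birth_t, end=None, state="censored",
            t=[], L=[], F=[], F2=[], x=x, y=y,
        ))
        return i

    def div_target(birth_len: float) -> float:
        jitter = math.exp(rng.normal(0.0, params.div_size_cv)) \
            if params.div_size_cv > 0 else 1.0
        return 2.0 * birth_len * jitter

    ros = _Roster()
    founder = new_record(None, 0.0, 500.0, 500.0)
    ros.length = np.array([params.birth_length])
    ros.D_in = np.zeros(1)
    ros.S = np.array([params.basal_damage])   # basal misfolding steady state
    # start the reporter at its stochastic steady state around f_eq
    ros.F = np.array([max(f_eq * math.exp(0.2 * rng.standard_normal()), 1e-6)])
    ros.F2 = np.zeros(1)
    ros.vigor = np.array([
        math.exp(rng.normal(0.0, params.vigor_cv)) if params.vigor_cv > 0
        else 1.0])
    ros.birth_len = ros.length.copy()
    ros.div_target = np.array([div_target(params.birth_length)])
    ros.arrest_min = np.zeros(1)
    ros.arrested = np.zeros(1, dtype=bool)
    ros.rec_idx = [founder]

    induced = False
    induction_time: float | None = None
    d_out = 0.0
    clamp_counter: list = []
    t = 0.0
    has_stress = params.drug_outside > 0 or params.inducer_outside > 0

    while True:
        # --- divisions take effect at the frame boundary -------------------
        due = np.nonzero(~ros.arrested & (ros.length >= ros.div_target))[0]
        if len(due):
            keep = np.setdiff1d(np.arange(len(ros.length)), due)
            new_states, new_meta = [], []
            for i in due:
                ri = ros.rec_idx[i]
                records[ri]["end"] = t
                records[ri]["state"] = "divided"
                mother = CellState(ros.length[i], ros.D_in[i], ros.S[i],
                                   ros.F[i], ros.F2[i])
                d1, d2 = divide_cell(mother, params, rng)
                if params.vigor_cv > 0:
                    rho = params.vigor_inheritance
                    sd = params.vigor_cv * math.sqrt(1.0 - rho ** 2)
                    vigs = [math.exp(rho * math.log(ros.vigor[i])
                                     + rng.normal(0.0, sd)) for _ in range(2)]
                else:
                    vigs = [1.0, 1.0]
                theta = rng.uniform(0.0, 2.0 * math.pi)
                off = ros.length[i] * params.px_per_um * 0.6
                x0, y0 = records[ri]["x"], records[ri]["y"]
                pos = [(x0, y0),
                       (x0 + off * math.cos(theta), y0 + off * math.sin(theta))]
                for d, vg, (px, py) in zip((d1, d2), vigs, pos):
                    j = new_record(ri, t, px, py)
                    new_states.append((d, vg, j))
            for f in _Roster.FIELDS:
                setattr(ros, f, getattr(ros, f)[keep])
            ros.arrested = ros.arrested[keep]
            ros.rec_idx = [ros.rec_idx[i] for i in keep]
            for d, vg, j in new_states:
                ros.length = np.append(ros.length, d.length)
                ros.D_in = np.append(ros.D_in, d.D_in)
                ros.S = np.append(ros.S, d.S)
                ros.F = np.append(ros.F, d.F)
                ros.F2 = np.append(ros.F2, d.F2)
                ros.vigor = np.append(ros.vigor, vg)
                ros.birth_len = np.append(ros.birth_len, d.length)
                ros.div_target = np.append(ros.div_target, div_target(d.length))
                ros.arrest_min = np.append(ros.arrest_min, 0.0)
                ros.arrested = np.append(ros.arrested, False)
                ros.rec_idx.append(j)

        n_alive = len(ros.length)
        if n_alive == 0:
            raise SimulationError(f"colony extinct (seed state: {rng})")

        # --- stress induction ----------------------------------------------
        if has_stress and not induced and n_alive >= params.induction_colony_size:
            induced = True
            induction_time = t
            d_out = params.drug_outside

        # --- record the frame ----------------------------------------------
        for i, ri in enumerate(ros.rec_idx):
            rec = records[ri]
            rec["t"].append(t)
            rec["L"].append(ros.length[i])
            rec["F"].append(ros.F[i])
            rec["F2"].append(ros.F2[i])

        if n_alive >= params.max_colony_size or t >= params.t_max - 1e-9:
            break

        # --- integrate to the next frame ------------------------------------
        state = CellState(ros.length, ros.D_in, ros.S, ros.F, ros.F2)
        for _ in range(params.n_substeps):
            state = step_cell(state, params, dt, d_out, rng, ros.vigor,
                              clamp_counter)
        ros.length, ros.D_in, ros.S = state.length, state.D_in, state.S
        ros.F, ros.F2 = state.F, state.F2
        k_now = growth_rate_from_stress(ros.S, params, ros.vigor)
        slow = k_now < params.death_rate_floor
        ros.arrest_min = np.where(slow, ros.arrest_min + params.frame_interval,
                                  0.0)
        ros.arrested |= ros.arrest_min >= params.arrest_duration
        t = round(t + params.frame_interval, 9)

    for i, ri in enumerate(ros.rec_idx):
        records[ri]["state"] = "arrested" if ros.arrested[i] else "censored"
        records[ri]["end"] = t + params.frame_interval

    cells: dict[str, CellRecord] = {}
    with_f2 = params.inducer_outside > 0
    for rec in records:
        nt = len(rec["t"])
        fluor = {"yfp": np.array(rec["F"])}
        if with_f2:
            fluor["tet"] = np.array(rec["F2"])
        samples = SampleTable(
            np.array(rec["t"]), np.array(rec["L"]),
            np.full(nt, rec["x"]), np.full(nt, rec["y"]),
            fluor,
        )
        cells[rec["cell_id"]] = CellRecord(
            rec["cell_id"], rec["parent_id"], rec["birth"], rec["end"],
            rec["state"], samples)
    tree = LineageTree(cells, records[0]["cell_id"], induction_time,
                       params.frame_interval)
    tree.validate()
    return tree


def simulate_forest(params: SimParams, n_trees: int, seed: int = 0):
    """Independent replicate colonies with per-tree derived seeds."""
    return [
        simulate_tree(params, np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,))))
        for i in range(n_trees)
    ]


# ---------------------------------------------------------------------------
# Moment matching
# ---------------------------------------------------------------------------

def _measure_moments(params, t_eval, n_trees, seed):
    vals = []
    for i, tree in enumerate(simulate_forest(params, n_trees, seed)):
        te = tree.frame_times()[-1] if t_eval is None else t_eval
        for cid in tree.cells_alive_at(te):
            rec = tree.cells[cid]
            vals.append(rec.samples.fluor["yfp"][rec.samples.nearest_index(te)])
    v = np.array(vals)
    return float(v.mean()), float(v.var(ddof=1))


def fit_moments(
    target_mean: float,
    target_var: float,
    params: SimParams,
    free_names=("expression_induced", "expression_noise"),
    t_eval: float | None = None,
    n_trees: int = 4,
    max_iter: int = 10,
    rel_tol: float = 0.05,
    seed: int = 0,
):
    """Tune named parameters so the simulated reporter matches target moments.

    Coordinate-descent with multiplicative damped updates: the first free
    parameter is scaled toward the target mean, the second toward the target
    variance (on the √ scale), re-measuring after each round on ``n_trees``
    replicate colonies.  Returns ``(params, (mean, var), n_iterations)``.
    Raises :class:`FitError` for infeasible targets or non-convergence, with
    the iteration trace in the message.
    """
    if target_mean <= 0 or target_var <= 0:
        raise FitError(
            f"infeasible targets mean={target_mean}, var={target_var}: both "
            f"must be positive for a noisy reporter")
    p = replace(params)
    trace = []
    m, v = _measure_moments(p, t_eval, n_trees, seed)
    if (abs(m / target_mean - 1.0) < rel_tol
            and abs(v / target_var - 1.0) < rel_tol):
        return p, (m, v), 0
    for it in range(1, max_iter + 1):
        updates = {}
        updates[free_names[0]] = getattr(p, free_names[0]) * \
            (target_mean / m) ** 0.8
        if len(free_names) > 1:
            updates[free_names[1]] = getattr(p, free_names[1]) * \
                (target_var / v) ** 0.4
        p = replace(p, **updates)
        m, v = _measure_moments(p, t_eval, n_trees, seed)
        trace.append((it, m, v))
        if (abs(m / target_mean - 1.0) < rel_tol
                and abs(v / target_var - 1.0) < rel_tol):
            return p, (m, v), it
    raise FitError(
        f"moment matching did not converge in {max_iter} iterations; "
        f"trace={trace}")
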