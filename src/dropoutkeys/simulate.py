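"""Ground-truth generator: generalized Lotka-Volterra serial-dilution batches.

The generator emulates the dropout-experiment design end to end: a 12-strain
community plus all single-strain dropouts, grown in one or more "media"
(environments with distinct parameter sets) for four days with a 1:100
dilution into fresh medium every 24 h, sampled at 96 h, and observed through
the qPCR model (strain-specific 16S copy numbers, lognormal measurement
noise, detection-limit censoring).

Dynamics within one batch (passage) follow a gLV core with two mechanism
plugins mirroring the two keystone mechanisms the analysis pipeline must
recover:

* exclusive-resource acidification — one degrader strain consumes a
  polysaccharide pool R; fermentation acid lowers the culture pH
  (pH = pH0 - gamma_R (R0 - R) - accumulated biomass-linked acid), and each
  strain's growth is multiplied by a logistic switch g_i(pH) centered on its
  pH-sensitivity threshold. Removing the degrader keeps the medium mild and
  rescues the pH-sensitive strain.
* bacteriocin killing — a producer strain kills sensitive strains by mass
  action (-k_pi x_p x_i). Removing the producer (or zeroing the kill rate,
  the toxin-deletion analogue) releases the targets.

This module is test scaffolding with known ground truth, not an inference
claim: no dynamical model is fitted to real data anywhere in the package.

Abundances are integrated in scaled units of 1e9 genome equivalents per ml.
All randomness flows from a master seed through named substreams (inoculum
jitter, observation noise, metabolite noise) so each source can be frozen
independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .qpcr import normalize_qpcr, simulate_readout
from .types import AbundanceTable, CommunityDesign, StrainInfo, ValidationError

#: abundance unit used inside the integrator (genome equivalents per ml)
ABUNDANCE_SCALE = 1e9

#: extinction floor in scaled units; 1e-9 scaled = 1 cell per ml of culture,
#: below which a population cannot re-seed the next passage
EXTINCTION_FLOOR = 1e-9


@dataclass(frozen=True)
class Bacteriocin:
    """Mass-action interference killing by one producer strain."""

    producer: str
    kill_rates: Mapping[str, float]  # target strain -> rate per (scaled abundance * h)

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.kill_rates.values()):
            raise ValidationError("kill rates must be >= 0")


@dataclass(frozen=True)
class ExclusiveResource:
    """Polysaccharide pool degraded by one strain, acidifying the medium."""

    degrader: str
    resource0: float  # g/L in fresh medium
    uptake_rate: float  # per (scaled abundance * h)
    acid_per_resource: float  # pH units released per g/L consumed (gamma)
    growth_boost: float = 0.0  # extra growth rate for the degrader while R > 0


@dataclass
class EnvironmentParams:
    """One medium: gLV parameters plus mechanism plugins."""

    name: str
    mu: np.ndarray  # max growth rates, 1/h
    interactions: np.ndarray  # a_ij, per scaled abundance per h; a_ii < 0
    x0: np.ndarray  # inoculum, scaled units
    ph0: float = 7.0
    acid_rates: np.ndarray | None = None  # beta_i, pH units per unit biomass formed
    ph_thresholds: np.ndarray | None = None  # theta_i; NaN = insensitive
    ph_steepness: float = 8.0
    resource: ExclusiveResource | None = None
    bacteriocins: tuple[Bacteriocin, ...] = ()

    def validate(self, n: int) -> None:
        if self.mu.shape != (n,) or self.x0.shape != (n,):
            raise ValidationError("mu and x0 must have one entry per strain")
        if self.interactions.shape != (n, n):
            raise ValidationError("interaction matrix must be n x n")
        if not np.all(np.diag(self.interactions) < 0):
            raise ValidationError("self-interaction a_ii must be negative for every strain")
        if not np.all(np.isfinite(self.mu)) or not np.all(np.isfinite(self.interactions)):
            raise ValidationError("rates must be finite")


@dataclass
class SimulationScenario:
    """Complete specification of one in-silico dropout experiment."""

    roster: CommunityDesign
    environments: dict[str, EnvironmentParams]
    dilution: float = 100.0
    passage_hours: float = 24.0
    n_passages: int = 4
    n_bio: int = 3
    n_tech: int = 3
    obs_sigma: float = 0.2  # lognormal qPCR measurement noise
    inoculum_sigma: float = 0.05  # per-bio-replicate lognormal inoculum jitter
    ph_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution <= 1:
            raise ValidationError("dilution factor must be > 1")
        n = len(self.roster.roster)
        for env in self.environments.values():
            env.validate(n)

    def substream(self, name: str) -> np.random.Generator:
        import zlib

        return np.random.default_rng([self.seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _rhs_factory(env: EnvironmentParams, active: np.ndarray):
    n = env.mu.size
    mu = env.mu * active
    A = env.interactions
    beta = env.acid_rates if env.acid_rates is not None else np.zeros(n)
    theta = env.ph_thresholds if env.ph_thresholds is not None else np.full(n, np.nan)
    s = env.ph_steepness
    res = env.resource
    deg = None
    if res is not None and res.degrader in _ids_cache(env):
        deg = _ids_cache(env).index(res.degrader)
        if not active[deg]:
            deg = None
    kill = np.zeros((n, n))  # kill[p, i]
    ids = _ids_cache(env)
    for b in env.bacteriocins:
        p = ids.index(b.producer)
        if not active[p]:
            continue
        for t, k in b.kill_rates.items():
            kill[p, ids.index(t)] = k

    sensitive = ~np.isnan(theta)
    r0 = res.resource0 if res is not None else 0.0
    # the pH switch gates intrinsic growth AND incoming positive interactions
    # (cross-feeding needs active growth); inhibitory terms act regardless
    A_pos = np.where(A > 0, A, 0.0)
    np.fill_diagonal(A_pos, 0.0)
    A_neg = A - A_pos

    def rhs(t, y):
        x = np.maximum(y[:n], 0.0)
        R = max(y[n], 0.0)
        acid = y[n + 1]
        ph = env.ph0 - (res.acid_per_resource * (r0 - R) if res is not None else 0.0) - acid
        g = np.ones(n)
        if sensitive.any():
            g[sensitive] = 1.0 / (1.0 + np.exp(-s * (ph - theta[sensitive])))
        gated = mu + A_pos @ x
        if deg is not None and res.growth_boost > 0 and R > 1e-6:
            gated = gated.copy()
            gated[deg] += res.growth_boost
        net = g * gated + A_neg @ x
        kill_term = kill.T @ x  # per-capita kill rate on each strain
        dx = x * (net - kill_term)
        dR = -res.uptake_rate * x[deg] * R if (res is not None and deg is not None) else 0.0
        # acid release proportional to net biomass formation (fermentation-linked)
        dacid = float(beta @ (x * np.maximum(net - kill_term, 0.0)))
        return np.concatenate([dx, [dR, dacid]])

    return rhs


_env_ids: dict[int, list[str]] = {}


def _ids_cache(env: EnvironmentParams) -> list[str]:
    return _env_ids[id(env)]


def _register_ids(env: EnvironmentParams, ids: list[str]) -> None:
    _env_ids[id(env)] = ids


def simulate_passage(
    state: np.ndarray,
    env: EnvironmentParams,
    active: np.ndarray,
    hours: float,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate one 24 h batch; state = [x_1..x_n, R, acid]."""
    if np.any(state < 0):
        raise ValidationError("state must be non-negative")
    rhs = _rhs_factory(env, active)
    sol = solve_ivp(rhs, (0.0, hours), state, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integrator failed in {env.name}: {sol.message}; state={state!r}")
    end = sol.y[:, -1]
    end[: env.mu.size] = np.maximum(end[: env.mu.size], 0.0)
    return end


def run_community(
    scenario: SimulationScenario,
    env_name: str,
    dropout_of: str | None,
    inoculum_jitter: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Serial-dilution culture of one community.

    Returns (endpoint abundances in scaled units, endpoint pH, endpoint
    resource concentration). Extinction below the floor is set to exact 0
    at passage boundaries; each dilution resets resource and acid to the
    fresh-medium state.
    """
    env = scenario.environments[env_name]
    ids = scenario.roster.strain_ids
    _register_ids(env, ids)
    n = len(ids)
    active = np.array([sid != dropout_of for sid in ids], dtype=bool)
    x = env.x0 * active
    if inoculum_jitter is not None:
        x = x * inoculum_jitter
    res0 = env.resource.resource0 if env.resource is not None else 0.0
    state = np.concatenate([x, [res0, 0.0]])
    for p in range(scenario.n_passages):
        state = simulate_passage(state, env, active, scenario.passage_hours)
        if p < scenario.n_passages - 1:
            xs = state[:n] / scenario.dilution
            xs[xs < EXTINCTION_FLOOR] = 0.0
            state = np.concatenate([xs, [res0, 0.0]])  # fresh medium
    x_end = state[:n]
    x_end[x_end < EXTINCTION_FLOOR] = 0.0
    R_end, acid_end = float(state[n]), float(state[n + 1])
    gamma = env.resource.acid_per_resource if env.resource is not None else 0.0
    ph_end = env.ph0 - gamma * (res0 - R_end) - acid_end
    return x_end, float(ph_end), R_end


@dataclass
class ExperimentResult:
    abundance: AbundanceTable
    ph: pd.DataFrame  # sample_id, ph_spent, ph_fresh
    truth: pd.DataFrame  # true (noise-free) endpoints and planted signs
    resources: pd.DataFrame  # community, environment, resource_end, acid_end_ph


def _community_labels(
    roster: CommunityDesign, dropouts: Sequence[str] | None = None
) -> list[str | None]:
    if dropouts is None:
        return [None] + roster.strain_ids
    unknown = set(dropouts) - set(roster.strain_ids)
    if unknown:
        raise ValidationError(f"dropout strain(s) not in roster: {sorted(unknown)}")
    return [None] + list(dropouts)


def run_experiment(
    scenario: SimulationScenario, dropouts: Sequence[str] | None = None
) -> ExperimentResult:
    """Full consortium + every dropout x environments x replicates at 96 h.

    Biological replicates differ by lognormal inoculum jitter; technical
    replicates share the culture but draw independent qPCR observation
    noise. ``dropouts`` restricts the dropout communities simulated (the
    full consortium is always included). The truth table holds noise-free endpoint abundances per
    community and the planted relationship signs derived from them
    (>= 4-fold change or a detection-limit crossing).
    """
    roster = scenario.roster
    ids = roster.strain_ids
    n = len(ids)
    rng_inoc = scenario.substream("inoculum")
    rng_obs = scenario.substream("observation")
    rng_ph = scenario.substream("ph")

    data_rows, sample_rows, ph_rows, truth_rows, res_rows = [], [], [], [], []
    for env_name, env in scenario.environments.items():
        # noise-free reference endpoints for ground truth
        true_end: dict[str | None, np.ndarray] = {}
        for dropout in _community_labels(roster, dropouts):
            x_end, ph_end, r_end = run_community(scenario, env_name, dropout)
            true_end[dropout] = x_end
            comm = "full" if dropout is None else f"minus_{dropout}"
            res_rows.append(
                {
                    "community": comm,
                    "environment": env_name,
                    "resource_end": r_end,
                    "true_ph_end": ph_end,
                }
            )
            for i, sid in enumerate(ids):
                truth_rows.append(
                    {
                        "community": comm,
                        "environment": env_name,
                        "strain_id": sid,
                        "true_abundance": x_end[i] * ABUNDANCE_SCALE,
                        "true_ph": ph_end,
                    }
                )

        for dropout in _community_labels(roster, dropouts):
            comm = "full" if dropout is None else f"minus_{dropout}"
            for b in range(1, scenario.n_bio + 1):
                jitter = np.exp(rng_inoc.normal(0.0, scenario.inoculum_sigma, size=n))
                x_end, ph_end, _ = run_community(scenario, env_name, dropout, inoculum_jitter=jitter)
                for t in range(1, scenario.n_tech + 1):
                    sid_sample = f"{env_name}.{comm}.b{b}.t{t}"
                    sample_rows.append(
                        {
                            "sample_id": sid_sample,
                            "community": comm,
                            "environment": env_name,
                            "bio_replicate": b,
                            "tech_replicate": t,
                            "amount": 1.0,
                            "amount_unit": "ml",
                        }
                    )
                    ph_rows.append(
                        {
                            "sample_id": sid_sample,
                            "ph_spent": ph_end + float(rng_ph.normal(0.0, scenario.ph_noise)),
                            "ph_fresh": env.ph0,
                        }
                    )
                    for i, strain in enumerate(roster.roster):
                        readout = simulate_readout(
                            x_end[i] * ABUNDANCE_SCALE,
                            strain,
                            sample_id=sid_sample,
                            noise_sigma=scenario.obs_sigma if scenario.obs_sigma > 0 else 0.0,
                            rng=rng_obs if scenario.obs_sigma > 0 else None,
                        )
                        value, censored = normalize_qpcr(readout, strain)
                        data_rows.append(
                            {
                                "sample_id": sid_sample,
                                "strain_id": strain.strain_id,
                                "value": value,
                                "censored": censored,
                            }
                        )

    table = AbundanceTable(pd.DataFrame(data_rows), pd.DataFrame(sample_rows))
    truth = pd.DataFrame(truth_rows)
    truth = _attach_planted_signs(truth, roster)
    return ExperimentResult(
        abundance=table,
        ph=pd.DataFrame(ph_rows),
        truth=truth,
        resources=pd.DataFrame(res_rows),
    )


def observation_dtl_abundance(strain: StrainInfo) -> float:
    """The strain's DTL translated to the abundance (per ml) scale under the
    default observation parameters (20 ng/ul x 150 ul / 5 ng template, 1 ml):
    copies = abundance * n_16S / 600, so abundance_at_dtl = dtl * 600 / n_16S.
    """
    return strain.dtl * 600.0 / strain.n_16S


def _attach_planted_signs(truth: pd.DataFrame, roster: CommunityDesign) -> pd.DataFrame:
    """Planted relationship signs from noise-free endpoints.

    For each (x, y, environment): effect when the dropout/full abundance
    ratio is >= 4-fold, or when the pair crosses the observation detection
    limit (exclusion / positive_dependency analogues).
    """
    # DTL on the abundance scale under the default observation parameters:
    # copies = abundance * n_16S / 600  =>  abundance_at_dtl = dtl * 600 / n_16S
    dtl_abund = {s.strain_id: s.dtl * 600.0 / s.n_16S for s in roster.roster}
    full = truth[truth["community"] == "full"].set_index(["environment", "strain_id"])[
        "true_abundance"
    ]
    rows = []
    for (comm, env), grp in truth.groupby(["community", "environment"]):
        if not comm.startswith("minus_"):
            continue
        x = comm.removeprefix("minus_")
        for _, r in grp.iterrows():
            y = r["strain_id"]
            if y == x:
                continue
            a_drop = r["true_abundance"]
            a_full = float(full.loc[(env, y)])
            lim = dtl_abund[y]
            det_drop, det_full = a_drop >= lim, a_full >= lim
            if not det_drop and not det_full:
                sign = "below_DTL"
            elif det_drop and not det_full:
                sign = "exclusion"
            elif det_full and not det_drop:
                sign = "positive_dependency"
            else:
                ratio = a_drop / a_full
                if ratio >= 4.0:
                    sign = "negative"
                elif ratio <= 0.25:
                    sign = "positive"
                else:
                    sign = "none"
            rows.append(
                {
                    "community": comm,
                    "environment": env,
                    "strain_id": y,
                    "planted_sign": sign,
                }
            )
    return truth.merge(
        pd.DataFrame(rows), on=["community", "environment", "strain_id"], how="left"
    )
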