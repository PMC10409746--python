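"""Preset simulation scenarios and on-disk fixture bundles.

Two media are modeled with distinct interaction parameter sets, following
the study design of a glucose medium (called ``AF`` here) and a
polysaccharide medium (``APF``) that share the same base composition:

* In AF the bacteriocin producer (E.fa) dominates: one target (B.an) is
  killed outright (exclusion) and four more are suppressed several-fold.
  A lactic-acid producer (L.re) among the suppressed targets makes the
  producer's dropout *more* acidic than the full community.
* In APF the polysaccharide degrader (B.ca) has exclusive access to the
  resource pool; its fermentation acids drop the culture pH below the
  threshold of the most sensitive strain (M.in, excluded) and curtail
  three mildly sensitive strains. Bacteriocin efficacy is
  medium-dependent (as observed for real leaderless bacteriocins, which
  can be inactive in some media): it acts in AF only, so the producer is
  the dominant keystone in AF and the degrader in APF.
* A third mechanism shared by both media: a cross-feeder (B.co) supports
  M.in and F.pl.

All numbers below are the generator's fixed study conditions, chosen once
to mirror the magnitude of effects the dropout design is meant to detect
(multi-fold shifts and detection-limit crossings against ~20% measurement
noise); they are not fitted to any data set.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .qpcr import normalize_qpcr, simulate_readout
from .simulate import (
    ABUNDANCE_SCALE,
    Bacteriocin,
    EnvironmentParams,
    ExclusiveResource,
    ExperimentResult,
    SimulationScenario,
    run_experiment,
)
from .types import AbundanceTable, CommunityDesign, default_community

PRESETS = ("neutral", "AF_like_bacteriocin", "APF_like_acidification", "combined_two_media")

# Fixed per-strain baseline (order = DEFAULT_ROSTER):
#         E.fa  B.ca  B.co  M.in  B.an  F.pl  E.cl  C.in  L.re  A.muc T.mu  A.mur
_MU = np.array([0.70, 0.60, 0.50, 0.40, 0.45, 0.40, 0.50, 0.45, 0.55, 0.35, 0.40, 0.35])
_K = np.array([0.50, 0.40, 0.40, 0.15, 0.12, 0.10, 0.20, 0.15, 0.25, 0.10, 0.08, 0.06])
_X0 = np.full(12, 0.002)

_IDX = {s: i for i, s in enumerate(
    ["E.fa", "B.ca", "B.co", "M.in", "B.an", "F.pl", "E.cl", "C.in", "L.re", "A.muc", "T.mu", "A.mur"]
)}


def _base_interactions(weak_competition: float = 0.02) -> np.ndarray:
    """Logistic self-limitation plus weak diffuse competition."""
    A = np.zeros((12, 12))
    np.fill_diagonal(A, -_MU / _K)
    k_total = _K.sum()
    off = -weak_competition * (_MU / k_total)
    A += off[:, None] * (1 - np.eye(12))
    np.fill_diagonal(A, -_MU / _K)
    return A


def _crossfeed(A: np.ndarray) -> np.ndarray:
    """B.co supports M.in and F.pl (shared by both media).

    The positive gLV term raises the recipient's effective carrying capacity
    roughly (1 + a_cf x_Bco / mu)-fold while B.co sits near its own
    capacity, so a coefficient of 3.2 mu / K_Bco plants a ~4-fold positive
    relationship; the loop stays bounded because B.co is self-limited.
    """
    A = A.copy()
    for rec in ("M.in", "F.pl"):
        A[_IDX[rec], _IDX["B.co"]] = 3.2 * _MU[_IDX[rec]] / _K[_IDX["B.co"]]
    return A


_ENTEROCIN = Bacteriocin(
    producer="E.fa",
    kill_rates={"B.an": 8.0, "C.in": 0.7, "L.re": 0.9, "F.pl": 2.6, "E.cl": 0.8},
)

# biomass-linked acid release (pH units per unit scaled biomass formed)
_ACID = np.full(12, 0.25)
_ACID[_IDX["E.fa"]] = 0.9
_ACID[_IDX["L.re"]] = 2.2


def af_environment() -> EnvironmentParams:
    """Glucose-like medium: bacteriocin interference dominates."""
    A = _crossfeed(_base_interactions())
    # medium-specific competition: B.ca vs the mucin specialist
    A[_IDX["A.muc"], _IDX["B.ca"]] = -0.65  # ~4-fold suppression of A.muc at x_Bca ~ K_Bca
    return EnvironmentParams(
        name="AF",
        mu=_MU.copy(),
        interactions=A,
        x0=_X0.copy(),
        ph0=7.0,
        acid_rates=_ACID.copy(),
        bacteriocins=(_ENTEROCIN,),
    )


def apf_environment() -> EnvironmentParams:
    """Polysaccharide-like medium: exclusive-resource acidification plus bacteriocin."""
    A = _crossfeed(_base_interactions())
    theta = np.full(12, np.nan)
    # thresholds sit ~1 pH unit above the fully acidified culture and just
    # below the mild pH of the degrader's dropout, so only the degrader's
    # removal (a ~1-unit pH swing) rescues the sensitive strains; the small
    # pH shifts caused by removing minor acidifiers do not flip detection
    theta[_IDX["M.in"]] = 6.35
    theta[_IDX["C.in"]] = 6.15
    theta[_IDX["T.mu"]] = 6.20
    theta[_IDX["A.muc"]] = 6.10
    return EnvironmentParams(
        name="APF",
        mu=_MU.copy(),
        interactions=A,
        x0=_X0.copy(),
        ph0=7.0,
        # the APF carbohydrates are less readily fermented than glucose:
        # biomass-linked acid is halved, the polysaccharide fermentation
        # by the degrader supplies the bulk of the acidification
        acid_rates=0.5 * _ACID,
        ph_thresholds=theta,
        ph_steepness=8.0,
        resource=ExclusiveResource(
            degrader="B.ca",
            resource0=2.0,  # g/L polysaccharide
            uptake_rate=4.0,
            acid_per_resource=0.5,  # pH units per g/L fermented
            growth_boost=0.25,
        ),
        bacteriocins=(),  # toxin inactive in this medium (medium-dependent efficacy)
    )


def neutral_environment() -> EnvironmentParams:
    """No cross-strain interactions: every dropout leaves the rest unchanged."""
    A = np.zeros((12, 12))
    np.fill_diagonal(A, -_MU / _K)
    return EnvironmentParams(
        name="N1",
        mu=_MU.copy(),
        interactions=A,
        x0=_X0.copy(),
        ph0=7.0,
        acid_rates=np.full(12, 0.2),
    )


def build_scenario(preset: str, seed: int = 0, **overrides) -> SimulationScenario:
    if preset == "neutral":
        envs = {"N1": neutral_environment()}
    elif preset == "AF_like_bacteriocin":
        envs = {"AF": af_environment()}
    elif preset == "APF_like_acidification":
        envs = {"APF": apf_environment()}
    elif preset == "combined_two_media":
        envs = {"AF": af_environment(), "APF": apf_environment()}
    else:
        raise ValueError(f"unknown preset {preset!r}; available: {PRESETS}")
    return SimulationScenario(
        roster=default_community(), environments=envs, seed=seed, **overrides
    )


# ---------------------------------------------------------------------------
# observation-level generators (no ODE): calibration and recovery studies
# ---------------------------------------------------------------------------

def observation_table(
    true_full: np.ndarray,
    true_dropout: np.ndarray,
    focal: str,
    environment: str = "E1",
    n_wells: int = 9,
    sigma: float = 0.2,
    rng: np.random.Generator | None = None,
    roster: CommunityDesign | None = None,
) -> AbundanceTable:
    """Abundance table for one dropout-vs-full comparison from fixed true values.

    ``true_full`` / ``true_dropout`` are per-strain abundances per ml (the
    focal strain's dropout entry is ignored and set to 0). Each well draws
    independent lognormal observation noise and passes through the qPCR
    model, so detection-limit censoring applies.
    """
    roster = roster or default_community()
    rng = rng or np.random.default_rng(0)
    ids = roster.strain_ids
    data_rows, sample_rows = [], []
    for comm, truth in (("full", true_full), (f"minus_{focal}", true_dropout)):
        for w in range(n_wells):
            sid = f"{environment}.{comm}.w{w + 1}"
            sample_rows.append(
                {
                    "sample_id": sid,
                    "community": comm,
                    "environment": environment,
                    "bio_replicate": w // 3 + 1,
                    "tech_replicate": w % 3 + 1,
                    "amount": 1.0,
                    "amount_unit": "ml",
                }
            )
            for i, strain in enumerate(roster.roster):
                a = 0.0 if (comm != "full" and strain.strain_id == focal) else float(truth[i])
                readout = simulate_readout(
                    a, strain, sample_id=sid,
                    noise_sigma=sigma if a > 0 else 0.0,
                    rng=rng if a > 0 else None,
                )
                value, censored = normalize_qpcr(readout, strain)
                data_rows.append(
                    {"sample_id": sid, "strain_id": strain.strain_id, "value": value, "censored": censored}
                )
    return AbundanceTable(pd.DataFrame(data_rows), pd.DataFrame(sample_rows))


def null_dataset(seed: int, n_wells: int = 9, sigma: float = 0.2) -> AbundanceTable:
    """Dropout and full consortium drawn from the same distribution (no effect)."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x6E756C6C])
    base = _K * ABUNDANCE_SCALE
    return observation_table(base, base, focal="E.fa", n_wells=n_wells, sigma=sigma, rng=rng)


def planted_dataset(
    seed: int,
    n_planted: int = 3,
    fold: float = 10.0,
    sigma: float = 0.2,
    n_wells: int = 9,
) -> tuple[AbundanceTable, list[str]]:
    """Removal of the focal strain shifts ``n_planted`` strains by ``fold``.

    Planted strains alternate between increases (released from suppression)
    and decreases; the remaining strains are unaffected nulls. Returns the
    table and the planted strain ids.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x706C6E74])
    roster = default_community()
    ids = roster.strain_ids
    focal = "E.fa"
    others = [s for s in ids if s != focal]
    planted = others[:n_planted]
    base = _K * ABUNDANCE_SCALE
    dropout = base.copy()
    for j, sid in enumerate(planted):
        i = ids.index(sid)
        dropout[i] = base[i] * (fold if j % 2 == 0 else 1.0 / fold)
    return (
        observation_table(base, dropout, focal=focal, n_wells=n_wells, sigma=sigma, rng=rng),
        planted,
    )


# ---------------------------------------------------------------------------
# metabolite proxy table
# ---------------------------------------------------------------------------

#: feature -> (fresh-medium intensity, rule)
#: rules: consumed_by_degrader, produced_by_acidification, consumed_by_producer,
#:        consumed_by_all, inert, rare (mostly missing; exercises the NA filter)
_FEATURES = (
    [("inulin_proxy", 5e5, "consumed_by_degrader"),
     ("succinate_proxy", 2e4, "produced_by_acidification"),
     ("propionate_proxy", 1.5e4, "produced_by_acidification"),
     ("arginine", 3e5, "consumed_by_producer"),
     ("serine", 2.5e5, "consumed_by_producer"),
     ("glucose_proxy", 8e5, "consumed_by_all")]
    + [(f"feature_{i:03d}", 1e5, "inert") for i in range(1, 18)]
    + [(f"rare_{i:02d}", 5e4, "rare") for i in range(1, 8)]
)


def simulate_metabolite_table(result: ExperimentResult, scenario: SimulationScenario,
                              n_reps: int = 3, cv: float = 0.1) -> pd.DataFrame:
    """Spent-vs-fresh metabolite intensities consistent with the simulated cultures.

    One spent sample per (community, environment, biological replicate) plus
    ``n_reps`` fresh-medium references per environment. The degrader's
    resource consumption and the acidification read directly off the
    simulation state; amino-acid consumption follows the producer strain's
    presence (consumer flag). "rare" features are missing in most samples.
    """
    rng = scenario.substream("metabolites")
    res = result.resources.set_index(["community", "environment"])
    rows = []

    def noisy(x):
        return float(x * np.exp(rng.normal(0.0, cv)))

    for env_name, env in scenario.environments.items():
        r0 = env.resource.resource0 if env.resource is not None else 0.0
        for rep in range(1, n_reps + 1):
            row = {"sample_id": f"{env_name}.fresh.r{rep}", "role": "fresh_medium",
                   "community": "none", "environment": env_name}
            for feat, base, rule in _FEATURES:
                if rule == "rare":
                    row[feat] = np.nan
                elif rule == "produced_by_acidification":
                    row[feat] = noisy(base)
                else:
                    row[feat] = noisy(base)
            rows.append(row)
        for comm in sorted({c for c, e in res.index if e == env_name}):
            r_end = float(res.loc[(comm, env_name), "resource_end"])
            ph_end = float(res.loc[(comm, env_name), "true_ph_end"])
            acid_drop = env.ph0 - ph_end
            producer_present = comm != "minus_E.fa"
            for rep in range(1, n_reps + 1):
                row = {"sample_id": f"{env_name}.{comm}.r{rep}", "role": "community_spent",
                       "community": comm, "environment": env_name}
                for feat, base, rule in _FEATURES:
                    if rule == "consumed_by_degrader":
                        frac = (r_end / r0) if r0 > 0 else 1.0
                        row[feat] = noisy(base * max(frac, 0.01))
                    elif rule == "produced_by_acidification":
                        row[feat] = noisy(base * (1.0 + 40.0 * acid_drop))
                    elif rule == "consumed_by_producer":
                        row[feat] = noisy(base * (0.02 if producer_present else 1.0))
                    elif rule == "consumed_by_all":
                        row[feat] = noisy(base * 0.05)
                    elif rule == "rare":
                        row[feat] = noisy(base) if rng.random() < 0.1 else np.nan
                    else:
                        row[feat] = noisy(base)
                rows.append(row)
    return pd.DataFrame(rows)


def make_fixture(preset: str, seed: int, outdir: str | Path) -> Path:
    """Write the full CSV bundle for one preset; byte-identical for a fixed seed.

    Files: abundance.csv (+ abundance.samples.csv), ph.csv, metabolites.csv,
    truth.csv, roster.yaml, scenario.json.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {PRESETS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = build_scenario(preset, seed=seed)
    result = run_experiment(scenario)
    dio.write_abundance_table(result.abundance, outdir / "abundance.csv")
    dio._write_frame(result.ph, outdir / "ph.csv")
    metab = simulate_metabolite_table(result, scenario)
    dio._write_frame(metab, outdir / "metabolites.csv")
    dio._write_frame(result.truth, outdir / "truth.csv")
    dio.write_roster_config(scenario.roster, outdir / "roster.yaml")
    meta = {
        "preset": preset,
        "seed": seed,
        "environments": sorted(scenario.environments),
        "dilution": scenario.dilution,
        "passage_hours": scenario.passage_hours,
        "n_passages": scenario.n_passages,
        "n_bio": scenario.n_bio,
        "n_tech": scenario.n_tech,
        "obs_sigma": scenario.obs_sigma,
    }
    with open(outdir / "scenario.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return outdir
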