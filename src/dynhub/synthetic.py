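"""Synthetic two-group cohorts with known dynamic hub structure.

The generator emulates a resting-state fMRI study design — two groups
(53 NC + 40 SCD by default), 230 usable volumes at TR = 2 s, 90 atlas
regions — with a mechanism simple enough that every downstream quantity has
ground truth:

* Connectivity dynamics are discrete state switching.  Each latent state is
  a 90-region correlation matrix with a designated *hub set*: hub regions
  correlate at ``hub_strength`` (default 0.3) with every non-hub region and
  at ``hub_coherence`` (default 0.95) with each other, non-hub pairs at
  ``background_strength`` (default 0.1).  This is the correlation pattern
  of a one-factor model in which hubs load almost entirely on a shared
  signal (a hub cannot correlate more than sqrt(background) with dozens of
  mutually weakly-correlated regions — the Gram constraint caps
  ``hub_strength`` at ~0.316 for background 0.1, and positive definiteness
  is checked at config validation).  Volumes are drawn i.i.d. Gaussian from
  the active state's covariance (no autocorrelation model; the analysis is
  correlation-based and window-level).
* The state sequence is a resampling Markov chain: each volume the state is
  redrawn from the subject's stationary distribution with probability
  1/``dwell_mean`` (mean dwell 50 volumes = 100 s by default), else held.
  Per-subject stationary distributions are Dirichlet-jittered around the
  group's designed occupancy, giving realistic between-subject variation in
  hub probability.
* Group effects enter two ways: per-group state occupancies, and
  ``planted_group_effect`` — (region, delta) pairs realized for SCD
  subjects as an independent on/off overlay chain with stationary
  probability |delta| that adds (delta > 0) or suppresses (delta < 0) the
  region's hub rows while "on".
* Neuropsychological scores are linear in the subject's *realized* true hub
  probabilities of designated regions plus Gaussian noise, with group means
  and dispersions matching a typical SCD study demographic table.

Ground truth returned per cohort: each subject's state sequence and
realized per-region true hub probability (fraction of volumes in which the
region's rows were hub-elevated), plus the design-expected per-group hub
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import SubjectTimeSeries

GROUPS = ("NC", "SCD")


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class StateSpec:
    """One latent connectivity state: a hub set and per-group occupancy."""

    name: str
    hubs: tuple[int, ...]  # 1-based region indices
    occupancy: Mapping[str, float]  # group -> stationary weight


@dataclass(frozen=True)
class ScoreSpec:
    """One neuropsychological score: group means, couplings, noise."""

    name: str
    mean: Mapping[str, float]
    noise_sd: float
    coupled: tuple[tuple[int, float], ...] = ()  # (region, weight) pairs


@dataclass(frozen=True)
class CovariateModel:
    """Group-wise age / sex / education distributions."""

    age_mean: Mapping[str, float]
    age_sd: Mapping[str, float]
    female_frac: Mapping[str, float]
    education_mean: Mapping[str, float]
    education_sd: Mapping[str, float]


@dataclass
class SimulationConfig:
    states: Sequence[StateSpec]
    scores: Sequence[ScoreSpec]
    covariates: CovariateModel
    n_nc: int = 53
    n_scd: int = 40
    n_regions: int = 90
    n_volumes: int = 230
    tr_seconds: float = 2.0
    hub_strength: float = 0.3
    background_strength: float = 0.1
    hub_coherence: float = 0.95
    dwell_mean: float = 50.0
    occupancy_concentration: float = 20.0
    planted_group_effect: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_nc < 1 or self.n_scd < 1:
            raise ConfigError("need at least one subject per group")
        if self.n_volumes < 2:
            raise ConfigError("need at least 2 volumes")
        if self.dwell_mean < 1:
            raise ConfigError("dwell_mean must be >= 1 volume")
        if not self.states:
            raise ConfigError("need at least one state")
        for st in self.states:
            for g in GROUPS:
                if st.occupancy.get(g, 0) < 0:
                    raise ConfigError(f"state {st.name}: negative occupancy")
            for r in st.hubs:
                if not 1 <= r <= self.n_regions:
                    raise ConfigError(
                        f"state {st.name}: hub region {r} outside "
                        f"1..{self.n_regions}"
                    )
        for g in GROUPS:
            if sum(st.occupancy.get(g, 0) for st in self.states) <= 0:
                raise ConfigError(f"group {g}: occupancies sum to zero")
        for r, delta in self.planted_group_effect:
            if not 1 <= r <= self.n_regions:
                raise ConfigError(f"planted region {r} outside range")
            if not -1.0 <= delta <= 1.0:
                raise ConfigError(f"planted shift {delta} outside [-1, 1]")
        # every state covariance (with and without each overlay) must be
        # positive definite; fail here, not mid-simulation
        for st in self.states:
            _cholesky_for(frozenset(i - 1 for i in st.hubs), self)

    def occupancies(self, group: str) -> np.ndarray:
        w = np.array([st.occupancy.get(group, 0.0) for st in self.states], float)
        return w / w.sum()


def _correlation_matrix(hubs0: frozenset[int], config: SimulationConfig) -> np.ndarray:
    n, bg = config.n_regions, config.background_strength
    C = np.full((n, n), bg)
    idx = sorted(hubs0)
    C[idx, :] = config.hub_strength
    C[:, idx] = config.hub_strength
    C[np.ix_(idx, idx)] = config.hub_coherence
    np.fill_diagonal(C, 1.0)
    return C


def _cholesky_for(hubs0: frozenset[int], config: SimulationConfig) -> np.ndarray:
    C = _correlation_matrix(hubs0, config)
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ConfigError(
            f"state covariance with hub set {sorted(i + 1 for i in hubs0)} "
            "is not positive definite"
        ) from None


def expected_hub_prob(config: SimulationConfig, group: str) -> np.ndarray:
    """Design-expected per-region hub probability for a group.

    Base probability is the occupancy-weighted state-hub indicator; a
    positive planted overlay delta raises it to ``p + delta*(1-p)`` (union
    of independent processes), a negative one lowers it to
    ``p * (1 - |delta|)`` for SCD subjects.
    """
    occ = config.occupancies(group)
    p = np.zeros(config.n_regions)
    for w, st in zip(occ, config.states):
        for r in st.hubs:
            p[r - 1] += w
    if group == "SCD":
        for r, delta in config.planted_group_effect:
            if delta >= 0:
                p[r - 1] = p[r - 1] + delta * (1 - p[r - 1])
            else:
                p[r - 1] = p[r - 1] * (1 + delta)
    return p


def _markov_sequence(rng, T: int, stationary: np.ndarray, dwell_mean: float) -> np.ndarray:
    lam = 1.0 / dwell_mean
    k = len(stationary)
    seq = np.empty(T, dtype=int)
    cur = rng.choice(k, p=stationary)
    for t in range(T):
        if t > 0 and rng.random() < lam:
            cur = rng.choice(k, p=stationary)
        seq[t] = cur
    return seq


def generate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[SubjectTimeSeries], pd.DataFrame, dict]:
    """Draw a full cohort; returns (time series, phenotypes, ground truth).

    Deterministic given (config, seed): the same configuration and seed
    yield bit-identical outputs.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chol_cache: dict[frozenset[int], np.ndarray] = {}
    base_hubs = [frozenset(i - 1 for i in st.hubs) for st in config.states]
    expected = {g: expected_hub_prob(config, g) for g in GROUPS}
    T, n = config.n_volumes, config.n_regions
    cov = config.covariates

    cohort: list[SubjectTimeSeries] = []
    phen_rows = []
    true_probs = []
    state_seqs = []
    groups_per_subject = ["NC"] * config.n_nc + ["SCD"] * config.n_scd
    for s_idx, group in enumerate(groups_per_subject):
        sid = f"sub-{s_idx + 1:03d}"
        pi = rng.dirichlet(config.occupancy_concentration * config.occupancies(group))
        seq = _markov_sequence(rng, T, pi, config.dwell_mean)
        overlays = []
        if group == "SCD":
            for r, delta in config.planted_group_effect:
                on = _markov_sequence(
                    rng, T, np.array([1 - abs(delta), abs(delta)]),
                    config.dwell_mean,
                ).astype(bool)
                overlays.append((r - 1, np.sign(delta), on))
        keys = []
        for t in range(T):
            hub = set(base_hubs[seq[t]])
            for r0, sign, on in overlays:
                if on[t]:
                    (hub.add if sign > 0 else hub.discard)(r0)
            keys.append(frozenset(hub))
        data = np.empty((T, n))
        a = 0
        while a < T:
            b = a
            while b < T and keys[b] == keys[a]:
                b += 1
            key = keys[a]
            if key not in chol_cache:
                chol_cache[key] = _cholesky_for(key, config)
            data[a:b] = rng.standard_normal((b - a, n)) @ chol_cache[key].T
            a = b
        thp = np.zeros(n)
        for key in keys:
            for r0 in key:
                thp[r0] += 1
        thp /= T

        age = float(rng.normal(cov.age_mean[group], cov.age_sd[group]))
        sex = "F" if rng.random() < cov.female_frac[group] else "M"
        edu = float(max(0.0, rng.normal(cov.education_mean[group],
                                        cov.education_sd[group])))
        row = {"subject_id": sid, "group": group, "age": round(age, 1),
               "sex": sex, "education": round(edu, 1)}
        for sc in config.scores:
            val = sc.mean[group]
            for r, w in sc.coupled:
                val += w * (thp[r - 1] - expected[group][r - 1])
            val += rng.normal(0.0, sc.noise_sd)
            row[sc.name] = float(val)
        phen_rows.append(row)
        cohort.append(SubjectTimeSeries(sid, data, config.tr_seconds))
        true_probs.append(thp)
        state_seqs.append(seq)

    phenotypes = pd.DataFrame(phen_rows)
    ground_truth = {
        "subjects": [ts.subject_id for ts in cohort],
        "groups": groups_per_subject,
        "true_hub_prob": np.array(true_probs),
        "state_sequences": np.array(state_seqs),
        "expected_hub_prob": {g: expected[g] for g in GROUPS},
        "state_hubs": {st.name: list(st.hubs) for st in config.states},
        "planted_group_effect": list(config.planted_group_effect),
    }
    return cohort, phenotypes, ground_truth


# ---------------------------------------------------------------------------
# default configurations


def _default_covariates() -> CovariateModel:
    return CovariateModel(
        age_mean={"NC": 63.50, "SCD": 64.90},
        age_sd={"NC": 8.25, "SCD": 8.31},
        female_frac={"NC": 32 / 53, "SCD": 24 / 40},
        education_mean={"NC": 10.98, "SCD": 11.65},
        education_sd={"NC": 5.10, "SCD": 4.53},
    )


def _default_scores() -> tuple[ScoreSpec, ...]:
    # group means/sds follow the study demographic table; couplings tie the
    # memory/cognition scores to anterior-DMN and parietal hub probabilities
    return (
        ScoreSpec("AVLT-I", {"NC": 9.23, "SCD": 8.32}, 1.7, ((28, 4.0),)),
        ScoreSpec("AVLT-D", {"NC": 10.15, "SCD": 8.95}, 2.4, ((28, 5.0), (61, 3.0))),
        ScoreSpec("AVLT-R", {"NC": 12.00, "SCD": 11.18}, 2.3, ((61, 4.0),)),
        ScoreSpec("MMSE", {"NC": 28.19, "SCD": 28.05}, 1.9, ((23, 3.0),)),
        ScoreSpec("MoCA", {"NC": 26.22, "SCD": 25.51}, 2.5, ((25, 3.0), (67, 2.0))),
        ScoreSpec("CDT", {"NC": 2.64, "SCD": 2.57}, 0.6, ((33, 1.0),)),
        ScoreSpec("CDR", {"NC": 0.00, "SCD": 0.01}, 0.05),
        ScoreSpec("CES-DS", {"NC": 2.18, "SCD": 4.52}, 5.0),
        ScoreSpec("HIS", {"NC": 0.06, "SCD": 0.62}, 1.0),
        ScoreSpec("ADL", {"NC": 20.02, "SCD": 20.28}, 0.7),
    )


def _default_states(nc=(0.45, 0.35, 0.20), scd=(0.30, 0.40, 0.30)) -> tuple[StateSpec, ...]:
    return (
        StateSpec("anterior_dmn",
                  (23, 24, 25, 26, 27, 28, 33, 34),
                  {"NC": nc[0], "SCD": scd[0]}),
        StateSpec("posterior_dmn",
                  (35, 36, 61, 62, 65, 66, 67, 68),
                  {"NC": nc[1], "SCD": scd[1]}),
        StateSpec("visual_sensorimotor",
                  (1, 2, 43, 44, 47, 48, 49, 50),
                  {"NC": nc[2], "SCD": scd[2]}),
    )


def study_config(seed: int = 0) -> SimulationConfig:
    """Default cohort emulating the study design: 53 NC + 40 SCD, 230
    volumes at TR 2 s, reduced anterior-DMN state occupancy plus a +0.15
    left-hippocampus hub overlay in the SCD group."""
    return SimulationConfig(
        states=_default_states(),
        scores=_default_scores(),
        covariates=_default_covariates(),
        planted_group_effect=((37, 0.15),),
        seed=seed,
    )


def null_config(seed: int = 0, n_per_group: int = 30) -> SimulationConfig:
    """Both groups share the same dynamics: no occupancy difference, no
    planted effects.  Used for type-I-error calibration."""
    occ = (0.45, 0.35, 0.20)
    return SimulationConfig(
        states=_default_states(nc=occ, scd=occ),
        scores=_default_scores(),
        covariates=_default_covariates(),
        n_nc=n_per_group, n_scd=n_per_group,
        seed=seed,
    )


def planted_shift_config(
    seed: int = 0, region: int = 7, shift: float = 0.2, n_per_group: int = 30
) -> SimulationConfig:
    """Null dynamics plus one planted hub-probability shift in the SCD
    group, in a region that is hub in no base state (so the realized shift
    equals ``shift``).  Used for the power check."""
    cfg = null_config(seed=seed, n_per_group=n_per_group)
    cfg.planted_group_effect = ((region, shift),)
    return cfg


# ---------------------------------------------------------------------------
# fixed fixtures


def _toy5() -> SubjectTimeSeries:
    # deterministic 30 x 5 matrix; columns 1 and 2 are exact duplicates and
    # column 4 is an exact affine anti-image of column 3
    t = np.arange(30, dtype=float)
    a = np.sin(0.7 * t) + 0.05 * t
    b = np.cos(0.4 * t) + 0.02 * (t % 7)
    c = np.sin(1.3 * t + 0.5) - 0.03 * t
    data = np.column_stack([a, a.copy(), b, -b + 2.0, c])
    return SubjectTimeSeries("toy5", data, tr_seconds=2.0)


def _load_json(name: str) -> dict:
    with resources.files("dynhub.data").joinpath(name).open() as fh:
        return json.load(fh)


def fixed_fixture(name: str):
    """Packaged worked-example inputs, bit-identical across runs.

    Names: ``"toy5"`` (deterministic 30x5 series with a duplicated column
    pair), ``"table1_summaries"`` (demographic-table group summaries),
    ``"results_selections"`` (the four reported significance-based region
    selections; anterior members transcribed, non-anterior remainder a
    labelled synthetic completion).
    """
    if name == "toy5":
        return _toy5()
    if name == "table1_summaries":
        return _load_json("table1_summaries.json")
    if name == "results_selections":
        raw = _load_json("results_selections.json")
        out = {}
        for mode in ("dynamic", "static"):
            out[mode] = {}
            for group in GROUPS:
                entry = raw[mode][group]
                sel = sorted(entry["anterior"] + entry["completion_synthetic"])
                assert len(sel) == entry["n_reported"]
                out[mode][group] = {
                    "selected": sel,
                    "anterior": sorted(entry["anterior"]),
                    "completion_synthetic": sorted(entry["completion_synthetic"]),
                }
        return out
    raise KeyError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# configuration (de)serialization, used by the CLI


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["states"] = [
        {"name": st.name, "hubs": list(st.hubs),
         "occupancy": dict(st.occupancy)} for st in config.states
    ]
    d["scores"] = [
        {"name": sc.name, "mean": dict(sc.mean), "noise_sd": sc.noise_sd,
         "coupled": [list(c) for c in sc.coupled]} for sc in config.scores
    ]
    d["covariates"] = {k: dict(v) for k, v in asdict(config.covariates).items()}
    d["planted_group_effect"] = [list(p) for p in config.planted_group_effect]
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    base = study_config()
    states = tuple(
        StateSpec(s["name"], tuple(int(h) for h in s["hubs"]), dict(s["occupancy"]))
        for s in d.get("states", [])
    ) or tuple(base.states)
    scores = tuple(
        ScoreSpec(s["name"], dict(s["mean"]), float(s["noise_sd"]),
                  tuple((int(r), float(w)) for r, w in s.get("coupled", [])))
        for s in d.get("scores", [])
    ) or tuple(base.scores)
    cov = d.get("covariates")
    covariates = CovariateModel(**cov) if cov else base.covariates
    kwargs = {
        k: d[k] for k in (
            "n_nc", "n_scd", "n_regions", "n_volumes", "tr_seconds",
            "hub_strength", "background_strength", "hub_coherence", "dwell_mean",
            "occupancy_concentration", "seed",
        ) if k in d
    }
    planted = tuple(
        (int(r), float(delta)) for r, delta in d.get("planted_group_effect", [])
    )
    return SimulationConfig(states=states, scores=scores, covariates=covariates,
                            planted_group_effect=planted, **kwargs)
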