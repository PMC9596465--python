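"""Synthetic longitudinal cohorts with planted disease states.

The real complaint-mention data the pipeline was designed for is a
proprietary hospital EHR, so this module generates cohorts whose latent
structure is known exactly and can serve as ground truth for every pipeline
stage:

* a Zipf (power-law) background distribution over a complaint vocabulary,
  matching the rank-frequency law observed in clinical concept extraction;
* ``G`` latent disease states, each with a disjoint *signature* set of
  complaints whose probability is multiplied by ``signature_lift`` and
  renormalized — multimorbidity is expressed through mixture overlap, one
  true state per snapshot;
* an optional two-level hierarchy: sibling states share a parent-level
  signature block, which is what the dendrogram stage later recovers;
* Markov state dynamics over a row-stochastic transition matrix (geometric
  dwell times via self-transitions, absorbing end states allowed);
* per-bin Poisson mention counts, a configurable fraction of
  negative-polarity mentions, occasional empty bins (months without a
  visit), state-dependent clinical-event emission, and state-dependent
  demographics (age, sex, BMI).

Timestamps are integer day offsets from a per-patient index date; every
patient's first bin contains a positive mention at day 0, so downstream
30-day binning reproduces the generator's bins exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import CohortSpecError


def default_transition_matrix(
    n_states: int, self_prob: float = 0.6
) -> np.ndarray:
    """Uniform off-diagonal transitions with a common self-transition mass."""
    T = np.full((n_states, n_states), (1 - self_prob) / max(1, n_states - 1))
    np.fill_diagonal(T, self_prob if n_states > 1 else 1.0)
    return T


def chain_transition_matrix(
    n_states: int, advance_prob: float = 0.35
) -> np.ndarray:
    """A forward chain 0 -> 1 -> ... with geometric dwell; last state absorbs."""
    T = np.eye(n_states) * (1 - advance_prob)
    for i in range(n_states - 1):
        T[i, i + 1] = advance_prob
    T[-1, -1] = 1.0
    return T


@dataclass
class DemographicsModel:
    """Per-state demographic parameters (patient-level values are drawn from
    the patient's initial state; BMI follows the current state per bin)."""

    age_mean: np.ndarray  # years at index date
    age_sd: np.ndarray
    female_prop: np.ndarray
    bmi_mean: np.ndarray
    bmi_sd: np.ndarray
    bmi_obs_rate: float = 0.5  # probability a bin carries a BMI measurement

    @classmethod
    def uniform(cls, n_states: int) -> "DemographicsModel":
        return cls(
            age_mean=np.full(n_states, 60.0),
            age_sd=np.full(n_states, 10.0),
            female_prop=np.full(n_states, 0.45),
            bmi_mean=np.full(n_states, 27.0),
            bmi_sd=np.full(n_states, 4.0),
        )


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults are the conditions used
    throughout the package's own recovery experiments."""

    n_patients: int = 2000
    vocab_size: int = 500
    zipf_exponent: float = 1.5
    n_states: int = 4
    hierarchy: tuple[tuple[int, ...], ...] | None = None
    signature_size: int = 8
    signature_lift: float = 20.0
    parent_signature_size: int = 8
    transition_matrix: np.ndarray | None = None
    initial_distribution: np.ndarray | None = None
    mean_mentions_per_bin: float = 30.0
    neg_polarity_rate: float = 0.1
    empty_bin_rate: float = 0.05
    event_rates: dict[str, np.ndarray] = field(default_factory=dict)
    demographics_model: DemographicsModel | None = None
    timeline_length_distribution: tuple[str, float] = ("geometric", 0.16)
    signature_rank_offset: int = 10  # first background rank used for signatures
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.n_states)
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        if self.initial_distribution is None:
            self.initial_distribution = np.full(self.n_states, 1 / self.n_states)
        self.initial_distribution = np.asarray(self.initial_distribution, float)
        if self.demographics_model is None:
            self.demographics_model = DemographicsModel.uniform(self.n_states)
        self.validate()

    def validate(self) -> None:
        G = self.n_states
        for name in ("n_patients", "vocab_size", "n_states", "signature_size"):
            if getattr(self, name) <= 0:
                raise CohortSpecError(f"{name} must be positive")
        if self.zipf_exponent <= 0:
            raise CohortSpecError("zipf_exponent must be positive")
        if self.signature_lift < 1:
            raise CohortSpecError("signature_lift must be >= 1")
        T = self.transition_matrix
        if T.shape != (G, G):
            raise CohortSpecError("transition_matrix must be n_states x n_states")
        if (T < 0).any() or (T > 1).any():
            raise CohortSpecError("transition_matrix entries must lie in [0, 1]")
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
            raise CohortSpecError("transition_matrix rows must sum to 1 (tol 1e-12)")
        pi = self.initial_distribution
        if pi.shape != (G,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-12:
            raise CohortSpecError("initial_distribution must be a length-G distribution")
        for name in ("neg_polarity_rate", "empty_bin_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CohortSpecError(f"{name} must lie in [0, 1]")
        for ev, rates in self.event_rates.items():
            r = np.asarray(rates, float)
            if r.shape != (G,) or (r < 0).any() or (r > 1).any():
                raise CohortSpecError(
                    f"event_rates[{ev!r}] must be G probabilities in [0, 1]"
                )
        if self.hierarchy is not None:
            seen: set[int] = set()
            for group in self.hierarchy:
                for s in group:
                    if s in seen:
                        raise CohortSpecError("hierarchy assigns a state twice")
                    seen.add(s)
            if seen != set(range(G)):
                raise CohortSpecError("hierarchy must cover every state exactly once")
        needed = self.signature_rank_offset + G * self.signature_size
        if self.hierarchy is not None:
            needed += len(self.hierarchy) * self.parent_signature_size
        if needed > self.vocab_size:
            raise CohortSpecError(
                "vocab_size too small for the requested signature layout"
            )

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["transition_matrix"] = self.transition_matrix.tolist()
        d["initial_distribution"] = self.initial_distribution.tolist()
        d["event_rates"] = {k: np.asarray(v).tolist() for k, v in self.event_rates.items()}
        dm = d["demographics_model"]
        for k, v in dm.items():
            if isinstance(v, np.ndarray):
                dm[k] = v.tolist()
        return d


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    snapshot_states: pd.DataFrame  # patient_id, bin_index, state (non-empty bins)
    state_sequences: dict[str, list[int]]  # full per-bin sequence per patient
    signatures: dict[int, list[str]]  # state -> own+parent signature concepts
    hierarchy: tuple[tuple[int, ...], ...] | None
    transition_edges: list[tuple[int, int]]  # direct i -> j edges (i != j)
    event_rates: dict[str, list[float]]
    mixtures: np.ndarray  # G x V per-state complaint distributions


@dataclass
class SyntheticCohort:
    """Generated tables plus ground truth and the config echo."""

    mentions: pd.DataFrame
    events: pd.DataFrame
    demographics: pd.DataFrame
    bmi: pd.DataFrame
    truth: GroundTruth
    spec: CohortSpec

    def write(self, outdir: str | Path) -> None:
        """Write the three input tables as CSV, ground truth and config echo
        as JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.mentions.to_csv(out / "mentions.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.demographics.to_csv(out / "demographics.csv", index=False)
        self.bmi.to_csv(out / "bmi.csv", index=False)
        truth = {
            "snapshot_states": self.truth.snapshot_states.to_dict("list"),
            "signatures": {str(k): v for k, v in self.truth.signatures.items()},
            "hierarchy": self.truth.hierarchy,
            "transition_edges": self.truth.transition_edges,
            "event_rates": self.truth.event_rates,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth))
        (out / "config_echo.json").write_text(json.dumps(self.spec.to_jsonable()))


def _state_mixtures(spec: CohortSpec) -> tuple[np.ndarray, dict[int, list[str]], list[str]]:
    """Zipf background blended with lifted signature complaints.

    Signature blocks are carved from consecutive mid-frequency ranks
    (starting at ``signature_rank_offset``): first one block per hierarchy
    group (shared by its sibling states), then one disjoint block per state.
    """
    V, G = spec.vocab_size, spec.n_states
    ranks = np.arange(1, V + 1, dtype=float)
    background = ranks ** (-spec.zipf_exponent)
    background /= background.sum()
    vocab = [f"concept_{i:05d}" for i in range(V)]

    cursor = spec.signature_rank_offset
    parent_block: dict[int, np.ndarray] = {}
    if spec.hierarchy is not None:
        for group in spec.hierarchy:
            block = np.arange(cursor, cursor + spec.parent_signature_size)
            cursor += spec.parent_signature_size
            for s in group:
                parent_block[s] = block
    signatures: dict[int, list[str]] = {}
    mixtures = np.empty((G, V))
    for s in range(G):
        own = np.arange(cursor, cursor + spec.signature_size)
        cursor += spec.signature_size
        idx = np.concatenate([parent_block.get(s, np.empty(0, int)), own]).astype(int)
        w = background.copy()
        w[idx] *= spec.signature_lift
        mixtures[s] = w / w.sum()
        signatures[s] = [vocab[i] for i in idx]
    return mixtures, signatures, vocab


def _sample_timeline_length(spec: CohortSpec, rng: np.random.Generator) -> int:
    name, param = spec.timeline_length_distribution
    if name == "geometric":
        return int(rng.geometric(param))
    if name == "fixed":
        return int(param)
    if name == "poisson":
        return int(rng.poisson(param)) + 1
    raise CohortSpecError(
        f"timeline_length_distribution: unknown distribution {name!r}"
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort of complaint mentions, events, and demographics.

    Deterministic given ``spec.seed``.  Each patient's 30-day bins are
    consecutive integer day ranges; mention counts per non-empty bin are
    Poisson(``mean_mentions_per_bin``) with at least one mention forced into
    bin 0 (the anchoring mention, always positive polarity so binning stays
    aligned after polarity filtering).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mixtures, signatures, vocab = _state_mixtures(spec)
    G = spec.n_states
    T = spec.transition_matrix
    dm = spec.demographics_model
    bin_w = 30

    mention_rows: list[pd.DataFrame] = []
    event_rows: list[tuple] = []
    demo_rows: list[tuple] = []
    bmi_rows: list[tuple] = []
    snap_state_rows: list[tuple] = []
    sequences: dict[str, list[int]] = {}
    event_names = sorted(spec.event_rates)

    for p in range(spec.n_patients):
        pid = f"P{p:06d}"
        n_bins = _sample_timeline_length(spec, rng)
        states = np.empty(n_bins, dtype=int)
        states[0] = rng.choice(G, p=spec.initial_distribution)
        for b in range(1, n_bins):
            states[b] = rng.choice(G, p=T[states[b - 1]])
        sequences[pid] = states.tolist()

        s0 = states[0]
        age_years = float(np.clip(rng.normal(dm.age_mean[s0], dm.age_sd[s0]), 0.5, 105))
        sex = "F" if rng.random() < dm.female_prop[s0] else "M"
        demo_rows.append((pid, -int(round(age_years * 365.25)), sex))

        empty = rng.random(n_bins) < spec.empty_bin_rate
        empty[0] = False
        n_mentions = rng.poisson(spec.mean_mentions_per_bin, size=n_bins)
        n_mentions[empty] = 0
        if n_mentions[0] == 0:
            n_mentions[0] = 1

        for b in range(n_bins):
            s = states[b]
            n = int(n_mentions[b])
            if n > 0:
                concept_counts = rng.multinomial(n, mixtures[s])
                concept_idx = np.repeat(np.arange(spec.vocab_size), concept_counts)
                rng.shuffle(concept_idx)
                days = b * bin_w + rng.integers(0, bin_w, size=n)
                neg = rng.random(n) < spec.neg_polarity_rate
                if b == 0:
                    days[0] = 0  # anchoring mention
                    neg[0] = False
                mention_rows.append(
                    pd.DataFrame(
                        {
                            "patient_id": pid,
                            "timestamp": days,
                            "concept_id": [vocab[i] for i in concept_idx],
                            "polarity": np.where(neg, "neg", "pos"),
                        }
                    )
                )
                n_pos = int(n - neg.sum())
                if b == 0:
                    n_pos = max(n_pos, 1)
                if n_pos > 0:
                    snap_state_rows.append((pid, b, int(s)))
            for ev in event_names:
                if rng.random() < spec.event_rates[ev][s]:
                    event_rows.append(
                        (pid, b * bin_w + int(rng.integers(0, bin_w)), ev)
                    )
            if rng.random() < dm.bmi_obs_rate:
                bmi_rows.append(
                    (
                        pid,
                        b * bin_w + int(rng.integers(0, bin_w)),
                        float(rng.normal(dm.bmi_mean[s], dm.bmi_sd[s])),
                    )
                )

    mentions = pd.concat(mention_rows, ignore_index=True)
    events = pd.DataFrame(event_rows, columns=["patient_id", "timestamp", "event_type"])
    demographics = pd.DataFrame(demo_rows, columns=["patient_id", "birth_date", "sex"])
    bmi = pd.DataFrame(bmi_rows, columns=["patient_id", "timestamp", "bmi"])
    truth = GroundTruth(
        snapshot_states=pd.DataFrame(
            snap_state_rows, columns=["patient_id", "bin_index", "state"]
        ),
        state_sequences=sequences,
        signatures=signatures,
        hierarchy=spec.hierarchy,
        transition_edges=[
            (i, j) for i in range(G) for j in range(G) if i != j and T[i, j] > 0
        ],
        event_rates={k: np.asarray(v).tolist() for k, v in spec.event_rates.items()},
        mixtures=mixtures,
    )
    return SyntheticCohort(mentions, events, demographics, bmi, truth, spec)
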