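"""Synthetic behavioral datasets with the assumed statistical structure.

The experimental learning-index means exist only as figure points, so the
fitting and recovery machinery runs on generated data: for every battery
condition the expected LI is computed from a ground-truth plasticity rule,
converted to the avoidance probability ``p = (LI + 1)/2``, and choice counts
are Bernoulli-sampled for ``n_fly`` flies in each of ``n_trial`` trials.
One master seed spawns an independent substream per condition, so adding a
condition never perturbs the draws of the others, and a dataset is
bit-identically reproducible from its provenance record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import empirical_index
from .fitting import FITTING_DT, battery_expected_li, theta_from_params, theta_fields
from .plasticity import BatteryArrays, PlasticityParams, pack_battery, paper_fit
from .protocols import StimulusProtocol, enumerate_experiment_battery

__all__ = [
    "BehavioralDataset",
    "generate_dataset",
    "make_noiseless_dataset",
    "make_paper_fixture",
    "DEFAULT_N_FLY",
    "DEFAULT_N_TRIAL",
]

#: default group size (experiments used groups of 60-100 flies)
DEFAULT_N_FLY = 80
#: default number of trials (groups) per condition
DEFAULT_N_TRIAL = 8


@dataclass
class BehavioralDataset:
    """Per-condition choice counts plus summary statistics and provenance.

    ``n_avoid``/``n_approach`` have shape (n_conditions, n_trial); for a
    noiseless dataset they are ``None`` and only the means are defined.
    """

    condition_ids: list[str]
    mean_index: np.ndarray
    sem: np.ndarray
    n_avoid: np.ndarray | None = None
    n_approach: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.condition_ids)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: condition_id, trial, n_avoid, n_approach."""
        if self.n_avoid is None:
            raise ValueError("noiseless dataset has no per-trial counts")
        rows = []
        for c, cid in enumerate(self.condition_ids):
            for trial in range(self.n_avoid.shape[1]):
                rows.append({"condition_id": cid, "trial": trial,
                             "n_avoid": int(self.n_avoid[c, trial]),
                             "n_approach": int(self.n_approach[c, trial])})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
        manifest = Path(path).with_suffix(".provenance.json")
        with open(manifest, "w") as fh:
            json.dump(self.provenance, fh, indent=2)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   provenance: dict | None = None) -> "BehavioralDataset":
        ids = list(dict.fromkeys(frame["condition_id"]))
        n_trial = int(frame["trial"].max()) + 1
        n_avoid = np.zeros((len(ids), n_trial), dtype=np.int64)
        n_approach = np.zeros_like(n_avoid)
        for c, cid in enumerate(ids):
            sub = frame[frame["condition_id"] == cid].sort_values("trial")
            n_avoid[c] = sub["n_avoid"].to_numpy()
            n_approach[c] = sub["n_approach"].to_numpy()
        return cls(ids, *_summaries(n_avoid, n_approach), n_avoid, n_approach,
                   provenance or {})

    @classmethod
    def from_csv(cls, path) -> "BehavioralDataset":
        manifest = Path(path).with_suffix(".provenance.json")
        provenance = {}
        if manifest.exists():
            with open(manifest) as fh:
                provenance = json.load(fh)
        return cls.from_frame(pd.read_csv(path), provenance)


def _summaries(n_avoid: np.ndarray, n_approach: np.ndarray):
    indices = empirical_index(n_avoid, n_approach)
    mean = indices.mean(axis=1)
    n_trial = indices.shape[1]
    sem = (indices.std(axis=1, ddof=1) / np.sqrt(n_trial)) if n_trial > 1 \
        else np.zeros(len(mean))
    return mean, sem


def _provenance(params: PlasticityParams, n_fly, n_trial, seed, dt) -> dict:
    return {
        "rule": params.rule,
        "params": {f: float(v) for f, v in
                   zip(theta_fields(params.rule), theta_from_params(params))},
        "n_fly": n_fly, "n_trial": n_trial, "seed": seed, "dt": dt,
    }


def generate_dataset(params: PlasticityParams,
                     battery: list[StimulusProtocol] | None = None,
                     n_fly: int = DEFAULT_N_FLY, n_trial: int = DEFAULT_N_TRIAL,
                     seed: int = 0, dt: float = FITTING_DT) -> BehavioralDataset:
    """Simulate learning and Bernoulli-sample choice counts per condition."""
    battery = battery if battery is not None else enumerate_experiment_battery(dt)
    batt = pack_battery(battery)
    li = battery_expected_li(params, batt)
    if not np.all(np.isfinite(li)):
        bad = [batt.names[i] for i in np.flatnonzero(~np.isfinite(li))]
        raise FloatingPointError(f"integration diverged for conditions: {bad}")
    p_avoid = (li + 1.0) / 2.0
    streams = np.random.SeedSequence(seed).spawn(len(battery))
    n_avoid = np.empty((len(battery), n_trial), dtype=np.int64)
    for c, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        n_avoid[c] = rng.binomial(n_fly, p_avoid[c], size=n_trial)
    n_approach = n_fly - n_avoid
    mean, sem = _summaries(n_avoid, n_approach)
    return BehavioralDataset(batt.names, mean, sem, n_avoid, n_approach,
                             _provenance(params, n_fly, n_trial, seed, batt.dt))


def make_noiseless_dataset(params: PlasticityParams,
                           battery: list[StimulusProtocol] | None = None,
                           dt: float = FITTING_DT) -> BehavioralDataset:
    """Dataset whose means ARE the analytic expected LIs (sem = 0).

    Used for exact self-consistency and parameter-recovery fixtures.
    """
    battery = battery if battery is not None else enumerate_experiment_battery(dt)
    batt = pack_battery(battery)
    li = battery_expected_li(params, batt)
    prov = _provenance(params, None, None, None, batt.dt)
    prov["noiseless"] = True
    return BehavioralDataset(batt.names, li, np.zeros_like(li), provenance=prov)


def make_paper_fixture(seed: int = 0, n_fly: int = DEFAULT_N_FLY,
                       n_trial: int = DEFAULT_N_TRIAL) -> BehavioralDataset:
    """The canonical packaged dataset: predictive rule, published parameters.

    ``make_paper_fixture(0)`` regenerates the CSV shipped under
    ``mbpredict/data/paper_fixture.csv`` bit-identically.
    """
    return generate_dataset(paper_fit("predictive"), n_fly=n_fly,
                            n_trial=n_trial, seed=seed)


def load_packaged_fixture() -> BehavioralDataset:
    """Load the committed canonical fixture from package data."""
    ref = resources.files("mbpredict").joinpath("data/paper_fixture.csv")
    with resources.as_file(ref) as path:
        return BehavioralDataset.from_csv(path)
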