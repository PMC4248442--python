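"""PM plate kinetics fixture: logistic respiration curves in three classes.

Each test well is assigned a growth class and a deterministic respiration
signal sampled every 15 min over 0-96 h:

* high:     logistic y(t) = A / (1 + exp(-k (t - t0))), A = 250 OU,
            k = 0.15 /h, t0 = 18 h
* moderate: logistic, A = 120 OU, k = 0.10 /h, t0 = 30 h
* none:     basal dye-settling transient 5 + 25 exp(-t / 20 h) OU -- the
            inoculum's residual respiration decaying to baseline; negative
            controls follow the same curve.

Growth wells get mild per-well jitter (A +/-5%, t0 +/-1.5 h) shared between
the two replicates; "none" wells jitter the transient amplitude.  Replicate
noise is additive Gaussian, independent per replicate, with a per-well
standard deviation proportional to the well's signal amplitude (respiration
readout noise grows with signal level).  The proportionality constant is
calibrated so that the mean noise variance across test wells equals
``pm_noise_ratio / (1 - pm_noise_ratio)`` times the cross-well variance of
the 48-h signal, which puts the expected cross-replicate correlation of the
48-h readout at 1 - pm_noise_ratio (0.93 by default).  Signals are clipped
at 0 OU.

Well A2 of the carbon plate is the D-glucose well, always in the high
class; it anchors the growth classifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..phenome import PlateSet
from .config import PLATE_LAYOUT, FixtureConfig
from .truth import GroundTruth

_STREAM = 2

CLASS_PARAMS = {
    "high": {"A": 250.0, "k": 0.15, "t0": 18.0},
    "moderate": {"A": 120.0, "k": 0.10, "t0": 30.0},
}
#: basal transient of no-growth wells and negative controls (OU)
BASAL_FLOOR_OU = 5.0
BASAL_AMPLITUDE_OU = 25.0
BASAL_DECAY_H = 20.0
TIME_GRID_H = np.arange(0, 96.25, 0.25)  # 15-min sampling, 385 points
GLUCOSE_CONDITION = "D-Glucose"
_A_JITTER = 0.05
_T0_JITTER_H = 1.5
#: nominal signal amplitude per class, scales the per-well noise sd
_NOISE_AMPLITUDE = {"high": 250.0, "moderate": 120.0, "none": 30.0}


def _all_wells() -> list[str]:
    return [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def _logistic(t: np.ndarray, A: float, k: float, t0: float) -> np.ndarray:
    return A / (1.0 + np.exp(-k * (t - t0)))


def _basal(t: np.ndarray, amplitude: float = BASAL_AMPLITUDE_OU) -> np.ndarray:
    return BASAL_FLOOR_OU + amplitude * np.exp(-t / BASAL_DECAY_H)


def generate_pm_plates(config: FixtureConfig) -> tuple[PlateSet, GroundTruth]:
    """Generate the three-plate, two-replicate kinetics fixture."""
    config.validate()
    rng = np.random.default_rng([_STREAM, config.seed])
    t = TIME_GRID_H

    # plate map: (plate, well, condition, role)
    map_rows: list[tuple[str, str, str, str]] = []
    counters = {"carbon": 0, "nitrogen": 0, "supplement": 0}
    for plate, layout in PLATE_LAYOUT.items():
        for well in _all_wells():
            if well in layout["controls"]:
                map_rows.append(
                    (plate, well, f"negative control {plate}-{well}", "negative_control")
                )
                continue
            kind = layout["kind"]
            counters[kind] += 1
            if plate == "PM1" and well == "A2":
                condition = GLUCOSE_CONDITION
            else:
                condition = f"{kind} source {counters[kind]:02d}"
            map_rows.append((plate, well, condition, "test"))
    plate_map = pd.DataFrame(map_rows, columns=["plate", "well", "condition", "role"])
    tests = plate_map[plate_map["role"] == "test"].reset_index(drop=True)

    classes = np.asarray(
        [c for c, n in sorted(config.pm_composition.items()) for _ in range(n)]
    )
    rng.shuffle(classes)
    glucose_pos = int(tests.index[tests["condition"] == GLUCOSE_CONDITION][0])
    if classes[glucose_pos] != "high":
        swap = int(np.flatnonzero(classes == "high")[0])
        classes[glucose_pos], classes[swap] = classes[swap], classes[glucose_pos]

    # deterministic per-well curves, jitter shared across replicates
    signals = np.empty((len(map_rows), t.size))
    noise_amp = np.empty(len(map_rows))
    truth = GroundTruth()
    n_test_seen = 0
    for i, (plate, well, condition, role) in enumerate(map_rows):
        if role == "test":
            cls = str(classes[n_test_seen])
            n_test_seen += 1
            truth.growth_class_by_well[(plate, well)] = cls
            truth.growth_class_by_condition[condition] = cls
        else:
            cls = "none"
        noise_amp[i] = _NOISE_AMPLITUDE[cls]
        if cls == "none":
            amp = BASAL_AMPLITUDE_OU * rng.uniform(1 - _A_JITTER, 1 + _A_JITTER)
            signals[i] = _basal(t, amp)
        else:
            p = CLASS_PARAMS[cls]
            A = p["A"] * rng.uniform(1 - _A_JITTER, 1 + _A_JITTER)
            t0 = p["t0"] + rng.uniform(-_T0_JITTER_H, _T0_JITTER_H)
            signals[i] = _logistic(t, A, p["k"], t0)

    # calibrate replicate noise against the cross-well 48-h signal variance
    i48 = int(np.flatnonzero(t == 48.0)[0])
    is_test = plate_map["role"].to_numpy() == "test"
    var_s = float(np.var(signals[is_test, i48]))
    ratio = config.pm_noise_ratio
    rel = noise_amp / _NOISE_AMPLITUDE["high"]
    if ratio > 0:
        base_sd = float(
            np.sqrt(ratio / (1.0 - ratio) * var_s / np.mean(rel[is_test] ** 2))
        )
    else:
        base_sd = 0.0
    well_sd = base_sd * rel

    frames = []
    for rep in (1, 2):
        if base_sd > 0:
            noise = rng.normal(0.0, 1.0, signals.shape) * well_sd[:, None]
        else:
            noise = np.zeros_like(signals)
        curves = np.clip(signals + noise, 0.0, None)
        frames.append(
            pd.DataFrame(
                {
                    "plate": np.repeat(plate_map["plate"].to_numpy(), t.size),
                    "well": np.repeat(plate_map["well"].to_numpy(), t.size),
                    "condition": np.repeat(plate_map["condition"].to_numpy(), t.size),
                    "replicate": rep,
                    "time_h": np.tile(t, len(map_rows)),
                    "omnilog_units": curves.ravel(),
                }
            )
        )
    kinetics = pd.concat(frames, ignore_index=True)
    return PlateSet(kinetics=kinetics, plate_map=plate_map), truth
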