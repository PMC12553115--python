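"""Synthetic 4D volumetric time series for the GLM / searchlight path.

Each PVT session becomes one run: an event sequence from the schedule,
per-voxel object amplitudes drawn from the same latent model as
:mod:`psmem.patterns`, a canonical double-gamma HRF response, slow linear
drift, rigid-body motion with optional injected spike volumes, and white
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._rng import child_rng
from .design import StudyDesign
from .patterns import GeneratorParams, _draw_latents
from .schedule import PvtSchedule

__all__ = ["SimulatedRun", "double_gamma_hrf", "make_regressor", "generate_timeseries"]

# SPM-style canonical double-gamma parameters (seconds)
HRF_PEAK_SHAPE = 6.0
HRF_UNDERSHOOT_SHAPE = 16.0
HRF_TIME_SCALE = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH = 32.0


@dataclass(frozen=True)
class SimulatedRun:
    """One simulated fMRI run (time is the last axis of ``data``)."""

    data: np.ndarray  # (nx, ny, nz, n_volumes)
    events: pd.DataFrame  # onset, duration, object_id, fly
    motion: np.ndarray  # (n_volumes, 6): 3 translations mm, 3 rotations rad
    tr: float
    amplitudes: np.ndarray  # (n_objects, n_voxels) ground truth
    spike_volumes: tuple[int, ...]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (s), peak-normalized."""
    t = np.asarray(t, dtype=float)

    def gpdf(x, shape, scale):
        x = np.where(x > 0, x, np.nan)
        out = np.exp((shape - 1) * np.log(x) - x / scale
                     - shape * np.log(scale) - gammaln(shape))
        return np.nan_to_num(out)

    h = gpdf(t, HRF_PEAK_SHAPE, HRF_TIME_SCALE) \
        - HRF_UNDERSHOOT_RATIO * gpdf(t, HRF_UNDERSHOOT_SHAPE, HRF_TIME_SCALE)
    peak = h.max()
    return h / peak if peak > 0 else h


def make_regressor(onsets: np.ndarray, durations: np.ndarray, n_volumes: int,
                   tr: float, oversample: int = 16) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at volume acquisition times."""
    if tr <= 0:
        raise ValueError("repetition time must be positive")
    dt = tr / oversample
    n_fine = n_volumes * oversample
    box = np.zeros(n_fine)
    for onset, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        box[i0:min(i1, n_fine)] = 1.0
    hrf = double_gamma_hrf(np.arange(0, HRF_LENGTH, dt))
    conv = np.convolve(box, hrf)[:n_fine] * dt
    return conv[::oversample][:n_volumes]


def schedule_events(schedule: PvtSchedule, session: int, stim_duration: float = 1.0,
                    isi: float = 2.0, initial_delay: float = 4.0) -> pd.DataFrame:
    """Event table (onset, duration, object_id, fly) for one session."""
    rows = []
    t = initial_delay
    for b, block in enumerate(schedule.blocks[session]):
        for oid in block:
            rows.append({"onset": t, "duration": stim_duration, "object_id": oid,
                         "fly": (session, b, oid) in schedule.fly_trials})
            t += stim_duration + isi
    return pd.DataFrame(rows)


def generate_timeseries(design: StudyDesign, schedule: PvtSchedule, params: GeneratorParams,
                        session: int = 0, day: str = "pre",
                        shape: tuple[int, int, int] = (6, 6, 6), tr: float = 1.0,
                        stim_duration: float = 1.0, isi: float = 2.0,
                        spike_volumes: tuple[int, ...] = (),
                        noise_sd: float | None = None,
                        amplitudes: np.ndarray | None = None,
                        n_blocks: int | None = None) -> SimulatedRun:
    """Simulate one run of the PVT.

    ``amplitudes`` (n_objects, prod(shape)) overrides the latent draw, which
    otherwise uses the pre-encoding latents for ``day='pre'`` and the
    post-encoding latents for ``day='post'``. ``n_blocks`` truncates the
    session for fast fixtures. Spike volumes get a 2 mm translation step,
    detectable as framewise-displacement outliers.
    """
    if tr <= 0:
        raise ValueError("repetition time must be positive")
    rng = child_rng(params.seed, "timeseries", design.participant_id, day, session)
    n_vox = int(np.prod(shape))
    if amplitudes is None:
        pre, post = _draw_latents(design, params, child_rng(params.seed, "ts-amplitudes",
                                                            design.participant_id), n_vox)
        amplitudes = pre if day == "pre" else post
    events = schedule_events(schedule, session, stim_duration, isi)
    if n_blocks is not None:
        events = events.iloc[: n_blocks * len(schedule.blocks[session][0])].reset_index(drop=True)
    total_t = float(events["onset"].iloc[-1] + stim_duration + 12.0)
    n_volumes = int(np.ceil(total_t / tr))

    signal = np.zeros((n_vox, n_volumes))
    for oid, grp in events[~events["fly"]].groupby("object_id"):
        reg = make_regressor(grp["onset"].to_numpy(), grp["duration"].to_numpy(),
                             n_volumes, tr)
        signal += np.outer(amplitudes[int(oid)], reg)
    fly_events = events[events["fly"]]
    if len(fly_events):
        reg = make_regressor(fly_events["onset"].to_numpy(),
                             fly_events["duration"].to_numpy(), n_volumes, tr)
        fly_amp = 0.5 * rng.standard_normal(n_vox)
        signal += np.outer(fly_amp, reg)

    drift = np.outer(0.01 * rng.standard_normal(n_vox), np.arange(n_volumes))
    sd = params.noise_sd if noise_sd is None else noise_sd
    data = signal + drift + sd * rng.standard_normal((n_vox, n_volumes))

    motion = np.cumsum(0.01 * rng.standard_normal((n_volumes, 6)), axis=0)
    motion[:, 3:] *= 0.002  # rotations stay small (radians)
    for k in spike_volumes:
        motion[k:, 0] += 2.0  # permanent 2 mm step -> FD spike exactly at k
    return SimulatedRun(
        data=data.reshape((*shape, n_volumes)),
        events=events,
        motion=motion,
        tr=tr,
        amplitudes=amplitudes,
        spike_volumes=tuple(int(k) for k in spike_volumes),
    )
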