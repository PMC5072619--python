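"""Single-nucleosome trajectory containers, file I/O and MSD estimators.

Trajectories are 2D single-particle-tracking tracks: per track, positions
``(x, y)`` in micrometres at consecutive frames with a fixed frame interval
(50 ms in the reference imaging conditions).  Files are plain delimited text
with a header row and columns ``track_id, frame, x_um, y_um``.

The primary MSD estimator is the origin-anchored ensemble average

    MSD(t_i) = (3/2) * (1/M_i) * sum_j [(x_i^j - x_0^j)^2 + (y_i^j - y_0^j)^2],

where ``M_i`` counts the tracks that survive at least ``i`` lags and the 3/2
factor converts the 2D projected displacement to a 3D value assuming
isotropy.  A conventional time-averaged estimator is provided for
comparison only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrackEnsemble",
    "MSDCurve",
    "read_tracks",
    "write_tracks",
    "ensemble_msd",
    "time_averaged_msd",
    "write_msd",
    "read_msd",
]

logger = logging.getLogger(__name__)

#: projection factor from 2D imaging plane to 3D displacement under isotropy
PROJECTION_FACTOR = 1.5


@dataclass
class TrackEnsemble:
    """A set of 2D single-nucleosome trajectories at a fixed frame interval.

    ``tracks`` is a list of ``(n_frames_i, 2)`` float arrays (x, y in um) at
    consecutive frames; ``track_ids`` the parallel list of identifiers.
    """

    tracks: list
    frame_interval: float = 0.05
    track_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        self.tracks = [np.asarray(tr, dtype=float) for tr in self.tracks]
        for tr in self.tracks:
            if tr.ndim != 2 or tr.shape[1] != 2:
                raise ValueError("each track must be an (n, 2) array of x, y positions")
            if tr.shape[0] < 2:
                raise ValueError("each track needs at least 2 frames")
            if not np.all(np.isfinite(tr)):
                raise ValueError("track positions must be finite")
        if not self.track_ids:
            self.track_ids = list(range(len(self.tracks)))
        elif len(self.track_ids) != len(self.tracks):
            raise ValueError("track_ids and tracks must have equal length")

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, tr in zip(self.track_ids, self.tracks):
            rows.append(
                pd.DataFrame(
                    {
                        "track_id": tid,
                        "frame": np.arange(tr.shape[0]),
                        "x_um": tr[:, 0],
                        "y_um": tr[:, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class MSDCurve:
    """Ensemble MSD vs lag time with per-lag SEM and sample counts."""

    lags: np.ndarray  # seconds
    msd: np.ndarray  # um^2
    sem: np.ndarray  # um^2
    n_tracks: np.ndarray  # M_i, contributing tracks per lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n_tracks = np.asarray(self.n_tracks, dtype=int)
        if not (len(self.lags) == len(self.msd) == len(self.sem) == len(self.n_tracks)):
            raise ValueError("all MSDCurve arrays must have equal length")
        if np.any(self.msd < 0) or np.any(self.sem < 0):
            raise ValueError("msd and sem must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_s": self.lags,
                "msd_um2": self.msd,
                "sem_um2": self.sem,
                "m_i": self.n_tracks,
            }
        )


def write_tracks(ensemble: TrackEnsemble, path, sep: str = ",") -> None:
    """Write an ensemble as delimited text (track_id, frame, x_um, y_um)."""
    ensemble.to_frame().to_csv(path, sep=sep, index=False)


def read_tracks(path, frame_interval: float = 0.05, sep: str = ",") -> TrackEnsemble:
    """Read a delimited track file into a :class:`TrackEnsemble`.

    Frames within a track must be consecutive; a gap splits the track into
    separate tracks (logged).  Non-monotone frames are an error.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track file {path} is missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"track file {path} contains no localizations")
    if df[["x_um", "y_um"]].abs().to_numpy().max() > 1000.0:
        logger.warning("positions exceed 1000 um; check that coordinates are in um")

    tracks, ids = [], []
    for tid, grp in df.groupby("track_id", sort=False):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {tid}: frames are not strictly increasing")
        xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        # split at frame gaps
        breaks = np.flatnonzero(np.diff(frames) > 1)
        segments = np.split(np.arange(len(frames)), breaks + 1)
        if len(segments) > 1:
            logger.warning(
                "track %s has %d frame gap(s); split into %d tracks",
                tid,
                len(segments) - 1,
                len(segments),
            )
        for k, seg in enumerate(segments):
            if len(seg) < 2:
                continue
            tracks.append(xy[seg])
            ids.append(tid if len(segments) == 1 else f"{tid}.{k}")
    if not tracks:
        raise ValueError(f"track file {path} contains no track with >= 2 frames")
    return TrackEnsemble(tracks=tracks, frame_interval=frame_interval, track_ids=ids)


def ensemble_msd(ensemble: TrackEnsemble, max_lag_frames: int | None = None) -> MSDCurve:
    """Origin-anchored ensemble-averaged MSD with the 3/2 isotropy factor.

    Displacements are measured from each track's first frame (not
    time-averaged).  ``SEM`` is the per-lag sample standard deviation of the
    per-track scaled squared displacements divided by ``sqrt(M_i)``.
    """
    if max_lag_frames is None:
        max_lag_frames = max(tr.shape[0] for tr in ensemble.tracks) - 1
    if max_lag_frames < 1:
        raise ValueError("max_lag_frames must be >= 1")

    lags, msd, sem, counts = [], [], [], []
    for i in range(1, max_lag_frames + 1):
        vals = [
            PROJECTION_FACTOR * float(np.sum((tr[i] - tr[0]) ** 2))
            for tr in ensemble.tracks
            if tr.shape[0] > i
        ]
        if not vals:
            continue
        vals = np.asarray(vals)
        m_i = vals.size
        lags.append(i * ensemble.frame_interval)
        msd.append(vals.mean())
        sem.append(vals.std(ddof=1) / np.sqrt(m_i) if m_i > 1 else 0.0)
        counts.append(m_i)
    if not lags:
        raise ValueError("no track is long enough for the requested lags")
    return MSDCurve(np.array(lags), np.array(msd), np.array(sem), np.array(counts))


def time_averaged_msd(ensemble: TrackEnsemble, max_lag_frames: int | None = None) -> MSDCurve:
    """Sliding-window (time-averaged) MSD, for comparison only.

    Per track, squared displacements are averaged over all start frames at
    each lag; the curve is the ensemble mean of the per-track averages, with
    SEM across tracks.  Not the estimator used for inference: the reference
    analysis anchors displacements at each track's first frame.
    """
    if max_lag_frames is None:
        max_lag_frames = max(tr.shape[0] for tr in ensemble.tracks) - 1
    if max_lag_frames < 1:
        raise ValueError("max_lag_frames must be >= 1")

    lags, msd, sem, counts = [], [], [], []
    for i in range(1, max_lag_frames + 1):
        vals = []
        for tr in ensemble.tracks:
            if tr.shape[0] <= i:
                continue
            disp = tr[i:] - tr[:-i]
            vals.append(PROJECTION_FACTOR * float(np.mean(np.sum(disp**2, axis=1))))
        if not vals:
            continue
        vals = np.asarray(vals)
        m_i = vals.size
        lags.append(i * ensemble.frame_interval)
        msd.append(vals.mean())
        sem.append(vals.std(ddof=1) / np.sqrt(m_i) if m_i > 1 else 0.0)
        counts.append(m_i)
    if not lags:
        raise ValueError("no track is long enough for the requested lags")
    return MSDCurve(np.array(lags), np.array(msd), np.array(sem), np.array(counts))


def write_msd(curve: MSDCurve, path, sep: str = ",") -> None:
    """Write an MSD curve as delimited text (lag_s, msd_um2, sem_um2, m_i)."""
    curve.to_frame().to_csv(path, sep=sep, index=False)


def read_msd(path, sep: str = ",") -> MSDCurve:
    """Read an MSD curve written by :func:`write_msd`."""
    df = pd.read_csv(path, sep=sep)
    required = {"lag_s", "msd_um2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MSD file {path} is missing columns: {sorted(missing)}")
    n = len(df)
    sem = df["sem_um2"].to_numpy() if "sem_um2" in df else np.zeros(n)
    m_i = df["m_i"].to_numpy() if "m_i" in df else np.ones(n, dtype=int)
    return MSDCurve(df["lag_s"].to_numpy(), df["msd_um2"].to_numpy(), sem, m_i)
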