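"""Raw trace I/O and conversion to the 14-channel 16x16 image the CNN eats.

Each channel's 256-point (resampled) time series is laid out row-major into
a 16x16 grid: time index t goes to row ``t // 16``, column ``t % 16``.
Flattening the image row-major therefore recovers the normalized resampled
trace exactly — the image is a reshaped time series, not a time-frequency
arrangement.

Normalization statistics default to the *training partition only* and are
then applied frozen to validation/test samples, so no information flows
back across the site or partition boundary.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, InvalidArgumentError
from .synthetic import N_CHANNELS, SensorTrace

IMAGE_SIDE = 16
IMAGE_LEN = IMAGE_SIDE * IMAGE_SIDE  # 256

SCHEMES = ("none", "per_channel_zscore", "per_channel_minmax")


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel statistics frozen from a training partition."""

    mean: np.ndarray  # (14,)
    sd: np.ndarray    # (14,)
    lo: np.ndarray    # (14,)
    hi: np.ndarray    # (14,)


@dataclass
class BreathprintImage:
    """A 14x16x16 breathprint tensor plus its normalization provenance."""

    sample_id: str
    tensor: np.ndarray  # (14, 16, 16)
    scheme: str = "none"
    stats_source: str = "self"  # "self" | "train_set"
    label: str | None = None
    site: str | None = None
    recruitment_time: int | None = None
    covariates: dict = field(default_factory=dict)
    partition: str | None = None   # set by the pipeline: train/validation/test/finetune
    augmented: bool = False

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape != (N_CHANNELS, IMAGE_SIDE, IMAGE_SIDE):
            raise InvalidArgumentError(
                f"tensor must be ({N_CHANNELS}, {IMAGE_SIDE}, {IMAGE_SIDE}), got {self.tensor.shape}"
            )
        if not np.all(np.isfinite(self.tensor)):
            raise InvalidArgumentError("image values must be finite")
        if self.scheme not in SCHEMES:
            raise InvalidArgumentError(f"scheme must be one of {SCHEMES}")

    @property
    def is_cancer(self) -> bool:
        return self.label == "lung_cancer"

    def flat(self) -> np.ndarray:
        """(14, 256) row-major flattening — the normalized time series."""
        return self.tensor.reshape(N_CHANNELS, IMAGE_LEN)

    def with_tensor(self, tensor: np.ndarray, augmented: bool = True) -> "BreathprintImage":
        return replace(self, tensor=tensor, augmented=augmented)


def resample_trace(trace: SensorTrace, target_length: int = IMAGE_LEN) -> SensorTrace:
    """Linearly interpolate every channel onto ``target_length`` even points.

    Endpoints are preserved; a trace already at the target length is
    returned value-identical.
    """
    T = trace.n_timepoints
    if T < 2:
        raise InvalidArgumentError("trace must have at least 2 time points")
    if T == target_length:
        return trace
    old = np.linspace(0.0, 1.0, T)
    new = np.linspace(0.0, 1.0, target_length)
    channels = np.vstack([np.interp(new, old, ch) for ch in trace.channels])
    return SensorTrace(
        sample_id=trace.sample_id,
        site=trace.site,
        label=trace.label,
        recruitment_time=trace.recruitment_time,
        channels=channels,
        covariates=trace.covariates,
    )


def fit_normalization(traces_or_images) -> NormalizationStats:
    """Pool per-channel mean/sd/min/max over a (training) sample list."""
    stacks = []
    for item in traces_or_images:
        arr = item.flat() if isinstance(item, BreathprintImage) else np.asarray(item.channels)
        stacks.append(arr.reshape(N_CHANNELS, -1))
    pooled = np.concatenate(stacks, axis=1)
    sd = pooled.std(axis=1)
    sd = np.where(sd == 0, 1.0, sd)
    rng_ = pooled.max(axis=1) - pooled.min(axis=1)
    return NormalizationStats(
        mean=pooled.mean(axis=1),
        sd=sd,
        lo=pooled.min(axis=1),
        hi=np.where(rng_ == 0, pooled.min(axis=1) + 1.0, pooled.max(axis=1)),
    )


def trace_to_image(
    trace: SensorTrace,
    scheme: str = "per_channel_zscore",
    train_stats: NormalizationStats | None = None,
    stats_source: str | None = None,
) -> BreathprintImage:
    """Grid a 256-point trace into 14x16x16 and normalize per channel.

    With ``train_stats`` supplied, statistics come from the training
    partition (source="train_set"); otherwise they are computed from the
    sample itself (source="self"). The z-score scheme with frozen training
    statistics is the pipeline default. Explicitly requesting
    ``stats_source="train_set"`` without supplying statistics is an error —
    statistics are never silently recomputed from non-training data.
    """
    if scheme not in SCHEMES:
        raise InvalidArgumentError(f"scheme must be one of {SCHEMES}")
    if stats_source == "train_set" and train_stats is None:
        raise InvalidArgumentError("stats_source='train_set' requires train_stats")
    if trace.n_timepoints != IMAGE_LEN:
        raise InvalidArgumentError(
            f"trace must have exactly {IMAGE_LEN} points (resample first), got {trace.n_timepoints}"
        )
    x = trace.channels.astype(float)
    if scheme == "none":
        source = "self"
    elif train_stats is not None:
        source = "train_set"
        if scheme == "per_channel_zscore":
            x = (x - train_stats.mean[:, None]) / train_stats.sd[:, None]
        else:
            x = (x - train_stats.lo[:, None]) / (train_stats.hi - train_stats.lo)[:, None]
    else:
        source = "self"
        if scheme == "per_channel_zscore":
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            sd = np.where(sd == 0, 1.0, sd)
            x = (x - mu) / sd
        else:
            lo = x.min(axis=1, keepdims=True)
            hi = x.max(axis=1, keepdims=True)
            span = np.where(hi - lo == 0, 1.0, hi - lo)
            x = (x - lo) / span
    tensor = x.reshape(N_CHANNELS, IMAGE_SIDE, IMAGE_SIDE)
    return BreathprintImage(
        sample_id=trace.sample_id,
        tensor=tensor,
        scheme=scheme,
        stats_source=source,
        label=trace.label,
        site=trace.site,
        recruitment_time=trace.recruitment_time,
        covariates=trace.covariates,
    )


def traces_to_images(
    traces,
    scheme: str = "per_channel_zscore",
    train_stats: NormalizationStats | None = None,
    target_length: int = IMAGE_LEN,
) -> list[BreathprintImage]:
    """Resample + image an entire cohort with one frozen statistics set."""
    return [trace_to_image(resample_trace(t, target_length), scheme, train_stats) for t in traces]


def _parse_comorbidities(s: str) -> set:
    return set(filter(None, s.split("|")))


def read_traces(data_path: str | Path, metadata_path: str | Path) -> list[SensorTrace]:
    """Read a cohort written by :func:`enosedx.synthetic.write_cohort`.

    Every metadata sample must have exactly 14 channels of equal length;
    violations raise :class:`FormatError` naming the offending sample.
    """
    data_path, metadata_path = Path(data_path), Path(metadata_path)
    series: dict[str, dict[int, dict[int, float]]] = defaultdict(lambda: defaultdict(dict))
    with open(data_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            series[row["sample_id"]][int(row["channel_index"])][int(row["time_index"])] = float(row["value"])

    traces = []
    with open(metadata_path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["sample_id"]
            if sid not in series:
                raise FormatError(f"sample {sid!r}: metadata row has no trace data")
            chans = series[sid]
            if sorted(chans) != list(range(1, N_CHANNELS + 1)):
                raise FormatError(
                    f"sample {sid!r}: expected channels 1..{N_CHANNELS}, found {sorted(chans)}"
                )
            lengths = {len(v) for v in chans.values()}
            if len(lengths) != 1:
                raise FormatError(f"sample {sid!r}: ragged channel lengths {sorted(lengths)}")
            T = lengths.pop()
            mat = np.empty((N_CHANNELS, T))
            for c in range(1, N_CHANNELS + 1):
                pts = chans[c]
                if sorted(pts) != list(range(T)):
                    raise FormatError(f"sample {sid!r}: channel {c} has non-contiguous time indices")
                mat[c - 1] = [pts[t] for t in range(T)]
            cov = {
                "age": float(row["age"]) if row.get("age") else None,
                "sex": row.get("sex", ""),
                "smoking": row.get("smoking", ""),
                "comorbidities": _parse_comorbidities(row.get("comorbidities", "")),
            }
            if row.get("histology"):
                cov["histology"] = row["histology"]
            if row.get("stage"):
                cov["stage"] = row["stage"]
            traces.append(
                SensorTrace(
                    sample_id=sid,
                    site=row["site"],
                    label=row["label"],
                    recruitment_time=int(row["recruitment_time"]),
                    channels=mat,
                    covariates=cov,
                )
            )
    known = {t.sample_id for t in traces}
    orphans = set(series) - known
    if orphans:
        raise FormatError(f"trace data without metadata for samples: {sorted(orphans)}")
    return traces


def write_images(images, path: str | Path) -> None:
    """Persist images as flat CSV: sample_id, channel, row, col, value."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "channel", "row", "col", "value"])
        for img in images:
            for c in range(N_CHANNELS):
                for r in range(IMAGE_SIDE):
                    for col in range(IMAGE_SIDE):
                        w.writerow([img.sample_id, c, r, col, repr(float(img.tensor[c, r, col]))])
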