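"""Core in-memory containers for multi-speaker articulatory–acoustic corpora.

An utterance pairs an electromagnetic-articulography (EMA) trajectory — the
3-D positions of sensor coils glued to the tongue, lips and jaw, sampled at
100 Hz — with the synchronously recorded mono speech waveform.  A corpus is a
list of utterances per speaker; parallel corpora share ``prompt_id`` values
across speakers (every speaker read the same stimulus sentence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Audio sample rate every corpus is normalised to on ingestion (Hz).
AUDIO_RATE = 22_050

#: Default EMA sampling rate (Hz).
EMA_RATE = 100.0

DEFAULT_SENSORS = ("TT", "TB", "TR", "UL", "LL", "JAW")
#: Spatial axes as stored: x posterior→anterior, y right→left, z inferior→superior.
DEFAULT_DIMS = ("x", "y", "z")

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class SensorLayout:
    """Ordered sensor names and spatial axis labels of an EMA recording."""

    sensor_names: tuple[str, ...] = DEFAULT_SENSORS
    dims: tuple[str, ...] = DEFAULT_DIMS

    def __post_init__(self) -> None:
        if len(set(self.sensor_names)) != len(self.sensor_names):
            raise ValueError("sensor names must be unique")
        if len(self.dims) != 3:
            raise ValueError("exactly 3 spatial axes expected")

    @property
    def n_channels(self) -> int:
        return len(self.sensor_names) * len(self.dims)

    def column_names(self) -> list[str]:
        """Sensor-major, axis-minor column labels, e.g. ``TT_x, TT_y, TT_z, TB_x, ...``"""
        return [f"{s}_{d}" for s in self.sensor_names for d in self.dims]

    def column(self, sensor: str, dim: str) -> int:
        return self.sensor_names.index(sensor) * len(self.dims) + self.dims.index(dim)


@dataclass
class EmaTrajectory:
    """Time series of landmark coordinates (mm) for the sensors of one utterance.

    ``samples`` is T × (n_sensors·3), columns ordered per :class:`SensorLayout`.
    """

    samples: np.ndarray
    rate: float = EMA_RATE
    layout: SensorLayout = field(default_factory=SensorLayout)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] < 2:
            raise ValueError("trajectory must be 2-D with at least 2 frames")
        if self.samples.shape[1] != self.layout.n_channels:
            raise ValueError(
                f"expected {self.layout.n_channels} channels, got {self.samples.shape[1]}"
            )
        if not np.isfinite(self.samples).all():
            raise ValueError("trajectory contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    def sensor_xyz(self, sensor: str) -> np.ndarray:
        """T × 3 slice for one sensor."""
        i = self.layout.sensor_names.index(sensor) * 3
        return self.samples[:, i : i + 3]

    def copy(self) -> "EmaTrajectory":
        return replace(self, samples=self.samples.copy())


@dataclass
class Utterance:
    utt_id: str
    speaker_id: str
    prompt_id: str
    ema: EmaTrajectory
    audio: np.ndarray
    audio_rate: int = AUDIO_RATE

    def __post_init__(self) -> None:
        self.audio = np.asarray(self.audio, dtype=np.float64)
        if self.audio.ndim != 1 or self.audio.size == 0:
            raise ValueError(f"{self.utt_id}: audio must be non-empty mono")

    @property
    def audio_duration(self) -> float:
        return self.audio.size / self.audio_rate


@dataclass
class SpeakerCorpus:
    """All utterances of one speaker plus an optional train/val/test split map."""

    speaker_id: str
    utterances: list[Utterance]
    split: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [u.utt_id for u in self.utterances]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.speaker_id}: duplicate utt_ids")
        if self.split is not None:
            self.validate_split()

    def validate_split(self) -> None:
        if self.split is None:
            raise ValueError(f"{self.speaker_id}: no split assigned")
        ids = {u.utt_id for u in self.utterances}
        if set(self.split) != ids:
            raise ValueError(f"{self.speaker_id}: split map must cover every utterance")
        bad = {v for v in self.split.values() if v not in SPLITS}
        if bad:
            raise ValueError(f"{self.speaker_id}: unknown split labels {sorted(bad)}")

    def subset(self, part: str) -> list[Utterance]:
        """Utterances of one split part, in corpus order."""
        if part not in SPLITS:
            raise ValueError(f"unknown split {part!r}")
        self.validate_split()
        assert self.split is not None
        return [u for u in self.utterances if self.split[u.utt_id] == part]

    def utterance(self, utt_id: str) -> Utterance:
        for u in self.utterances:
            if u.utt_id == utt_id:
                return u
        raise KeyError(utt_id)

    @property
    def prompt_ids(self) -> list[str]:
        return [u.prompt_id for u in self.utterances]

    def __len__(self) -> int:
        return len(self.utterances)
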