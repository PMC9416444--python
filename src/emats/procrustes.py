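"""Procrustes matching of articulatory landmark shapes.

Inter-speaker differences in vocal-tract geometry and sensor placement show
up as rigid offsets of the EMA point cloud: each speaker's landmarks are
(approximately) a translated, rotated — and, across head sizes, scaled —
version of a common configuration.  Procrustes matching removes those
nuisance degrees of freedom in the midsagittal plane: the pooled point cloud
of a sentence (or of a whole speaker) is translated so its centroid sits at
the origin and rotated so the segment from the lower-lip centroid to the
upper-lip centroid points along the vertical axis.  Scaling to unit size is
available but off by default (it was found to hurt rather than help).

The matching plane is vertical × anterior–posterior.  With the storage axis
convention (x posterior→anterior, y right→left, z inferior→superior) that
plane is spanned by the stored ``z`` and ``x`` columns; the lateral ``y``
column passes through untouched.  Within the plane we write coordinates as
(v, a) = (vertical, anterior–posterior).

Rotation convention (fixed): the transform applied to centred points is

    [v'] = [cos θ   sin θ] [β_v   0 ] [v − c_v]
    [a']   [−sin θ  cos θ] [ 0   β_a] [a − c_a]

so a positive θ rotates the point cloud clockwise in the (v, a) plane; e.g.
(v, a) = (1, 0) maps to (0, −1) under θ = 90°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EmaTrajectory, SpeakerCorpus

#: Stored axis labels spanning the matching plane: (vertical, anterior–posterior).
VERTICAL_DIM = "z"
ANTPOST_DIM = "x"

#: Lip sensors whose centroids define the vertical axis (upper above lower).
UPPER_LIP = "UL"
LOWER_LIP = "LL"

_LIP_TOL = 1e-9


@dataclass(frozen=True)
class ProcrustesParams:
    """Estimated matching parameters for one shape.

    ``c_v``/``c_a`` are the translation centroids (mm), ``theta`` the rotation
    (radians, in (−π, π]), ``beta_v``/``beta_a`` the scale factors (1 unless
    scaling was requested), ``level`` the pooling level the shape came from.
    """

    c_v: float
    c_a: float
    theta: float
    beta_v: float = 1.0
    beta_a: float = 1.0
    level: str = "sentence"

    def __post_init__(self) -> None:
        if not (self.beta_v > 0 and self.beta_a > 0):
            raise ValueError("scale factors must be positive")
        for name in ("c_v", "c_a", "theta"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, s], [-s, c]])

    def to_dict(self) -> dict:
        return {
            "c_v": self.c_v, "c_a": self.c_a, "theta": self.theta,
            "beta_v": self.beta_v, "beta_a": self.beta_a, "level": self.level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProcrustesParams":
        return cls(**d)


IDENTITY_PARAMS = ProcrustesParams(c_v=0.0, c_a=0.0, theta=0.0)


@dataclass
class Shape:
    """Pooled (v, a) landmark points of one sentence or one speaker.

    ``points`` is n × 2 with columns (vertical, anterior–posterior); ``sensor``
    is the length-n array of sensor labels so lip points remain identifiable.
    """

    points: np.ndarray
    sensor: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.sensor = np.asarray(self.sensor)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or self.points.shape[0] < 2:
            raise ValueError("shape needs >= 2 points with 2 coordinates")
        if self.sensor.shape[0] != self.points.shape[0]:
            raise ValueError("one sensor label per point required")
        if not np.isfinite(self.points).all():
            raise ValueError("shape coordinates must be finite")

    def sensor_centroid(self, name: str) -> np.ndarray:
        mask = self.sensor == name
        if not mask.any():
            raise ValueError(f"shape has no points for sensor {name!r}")
        return self.points[mask].mean(axis=0)


def shape_from_trajectories(trajectories: list[EmaTrajectory]) -> Shape:
    """Pool the (v, a) points of one or more trajectories into a Shape."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    pts, labels = [], []
    for ema in trajectories:
        lay = ema.layout
        for name in lay.sensor_names:
            v = ema.samples[:, lay.column(name, VERTICAL_DIM)]
            a = ema.samples[:, lay.column(name, ANTPOST_DIM)]
            pts.append(np.column_stack([v, a]))
            labels.append(np.full(v.size, name))
    return Shape(points=np.concatenate(pts), sensor=np.concatenate(labels))


def estimate_params(
    shape: Shape,
    lip_sensors: tuple[str, str] = (UPPER_LIP, LOWER_LIP),
    use_scale: bool = False,
    level: str = "sentence",
) -> ProcrustesParams:
    """Estimate translation, rotation and (optionally) scale from one shape.

    The centroid of all points gives the translation; the angle that carries
    the lower-lip→upper-lip centroid vector onto the positive vertical axis
    gives the rotation; scale factors are the reciprocals of the centred
    root-sum-of-squares per coordinate (so that applying them yields a
    unit-size shape).
    """
    upper, lower = lip_sensors
    c = shape.points.mean(axis=0)
    lip_vec = shape.sensor_centroid(upper) - shape.sensor_centroid(lower)
    if float(np.hypot(*lip_vec)) < _LIP_TOL:
        raise ValueError("upper- and lower-lip centroids coincide; rotation undefined")
    # R(theta) maps lip_vec onto +v  =>  theta = atan2(a-component, v-component)
    theta = float(np.arctan2(lip_vec[1], lip_vec[0]))
    beta_v = beta_a = 1.0
    if use_scale:
        centred = shape.points - c
        size_v = float(np.sqrt(np.sum(centred[:, 0] ** 2)))
        size_a = float(np.sqrt(np.sum(centred[:, 1] ** 2)))
        if size_v < _LIP_TOL or size_a < _LIP_TOL:
            raise ValueError("degenerate shape: zero extent along an axis")
        beta_v, beta_a = 1.0 / size_v, 1.0 / size_a
    return ProcrustesParams(
        c_v=float(c[0]), c_a=float(c[1]), theta=theta,
        beta_v=beta_v, beta_a=beta_a, level=level,
    )


def apply_matching(ema: EmaTrajectory, params: ProcrustesParams) -> EmaTrajectory:
    """Apply translate → scale → rotate to the (v, a) columns of every sensor.

    The lateral column is untouched; output length equals input length.
    """
    out = ema.samples.copy()
    R = params.rotation_matrix()
    lay = ema.layout
    for name in lay.sensor_names:
        iv, ia = lay.column(name, VERTICAL_DIM), lay.column(name, ANTPOST_DIM)
        v = (out[:, iv] - params.c_v) * params.beta_v
        a = (out[:, ia] - params.c_a) * params.beta_a
        out[:, iv] = R[0, 0] * v + R[0, 1] * a
        out[:, ia] = R[1, 0] * v + R[1, 1] * a
    return EmaTrajectory(samples=out, rate=ema.rate, layout=lay)


def unapply_matching(ema: EmaTrajectory, params: ProcrustesParams) -> EmaTrajectory:
    """Inverse of :func:`apply_matching` (used by the corpus generator)."""
    out = ema.samples.copy()
    Rinv = params.rotation_matrix().T
    lay = ema.layout
    for name in lay.sensor_names:
        iv, ia = lay.column(name, VERTICAL_DIM), lay.column(name, ANTPOST_DIM)
        v = out[:, iv]
        a = out[:, ia]
        rv = Rinv[0, 0] * v + Rinv[0, 1] * a
        ra = Rinv[1, 0] * v + Rinv[1, 1] * a
        out[:, iv] = rv / params.beta_v + params.c_v
        out[:, ia] = ra / params.beta_a + params.c_a
    return EmaTrajectory(samples=out, rate=ema.rate, layout=lay)


def match_corpus(
    corpora: list[SpeakerCorpus],
    level: str = "sentence",
    use_scale: bool = False,
) -> tuple[list[SpeakerCorpus], dict[str, dict[str, ProcrustesParams]]]:
    """Match every trajectory of every speaker to the canonical pose.

    sentence level
        Parameters are estimated independently per (speaker, sentence) from
        that sentence's own pooled points, bringing every sentence to the
        canonical pose (centroid at origin, lip axis vertical).  This
        self-normalisation needs no cross-speaker pairing, so it applies
        unchanged to unseen test sentences.
    speaker level
        Parameters are estimated once per speaker from the pooled points of
        that speaker's training sentences (all sentences if no split is
        assigned) and applied to all of the speaker's data.

    Returns transformed corpora plus a registry
    ``{speaker_id: {utt_id_or_'speaker': ProcrustesParams}}``.
    """
    if level not in ("sentence", "speaker"):
        raise ValueError(f"unknown level {level!r}")
    from dataclasses import replace as _replace

    matched: list[SpeakerCorpus] = []
    registry: dict[str, dict[str, ProcrustesParams]] = {}
    for corpus in corpora:
        reg: dict[str, ProcrustesParams] = {}
        new_utts = []
        if level == "speaker":
            pool = corpus.subset("train") if corpus.split is not None else corpus.utterances
            shape = shape_from_trajectories([u.ema for u in pool])
            params = estimate_params(shape, use_scale=use_scale, level="speaker")
            reg["speaker"] = params
            for u in corpus.utterances:
                new_utts.append(_replace(u, ema=apply_matching(u.ema, params)))
        else:
            for u in corpus.utterances:
                shape = shape_from_trajectories([u.ema])
                params = estimate_params(shape, use_scale=use_scale, level="sentence")
                reg[u.utt_id] = params
                new_utts.append(_replace(u, ema=apply_matching(u.ema, params)))
        matched.append(SpeakerCorpus(corpus.speaker_id, new_utts, dict(corpus.split) if corpus.split else None))
        registry[corpus.speaker_id] = reg
    return matched, registry
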