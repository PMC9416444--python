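"""Leave-one-subject-out speaker-adaptation experiment designs.

Seven designs are supported, named by what enters the articulation-to-speech
(ATS) training set and which adaptations are applied:

========  ============================================================
SD        target speaker's own training data only (speaker-dependent)
SI        source speakers only (speaker-independent baseline)
SI-P      SI + Procrustes matching of the articulatory input
SI-VC     SI with source acoustics converted to the target voice
SI-VC-P   both adaptations
SA-P      source + target training data, Procrustes matching
SA-VC-P   SA-P with source acoustics voice-converted
========  ============================================================

Each speaker takes a turn as the held-out target; the remaining speakers are
sources.  The chain per design: optional sentence-level Procrustes matching
of the EMA data, z-score normalisation of articulatory features (fitted on
the design's own training frames), optional voice conversion of source
acoustics via per source–target BLSTM models on DTW-aligned parallel
phrases, ATS training, and MCD evaluation on the target's test sentences.
Validation follows the design: speaker-independent designs validate on the
source speakers' validation sets, SD/SA designs on the target's.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features
from .alignment import dtw_align, warp_to_target
from .data import SpeakerCorpus
from .evaluation import EvaluationReport, mcd
from .models import (
    RegressorSpec,
    TrainedModel,
    default_spec,
    predict_sequence,
    train_regressor,
)
from .procrustes import match_corpus

DESIGN_NAMES = ("SD", "SI", "SI-P", "SI-VC", "SI-VC-P", "SA-P", "SA-VC-P")


@dataclass(frozen=True)
class DesignSpec:
    """Configuration of one experimental design."""

    name: str
    use_sources: bool
    include_target_train: bool
    procrustes: bool
    vc: bool
    zscore: bool = True

    def __post_init__(self) -> None:
        if not (self.use_sources or self.include_target_train):
            raise ValueError(f"{self.name}: design has an empty training set")


_DESIGNS = {
    "SD": DesignSpec("SD", use_sources=False, include_target_train=True,
                     procrustes=False, vc=False),
    "SI": DesignSpec("SI", use_sources=True, include_target_train=False,
                     procrustes=False, vc=False),
    "SI-P": DesignSpec("SI-P", use_sources=True, include_target_train=False,
                       procrustes=True, vc=False),
    "SI-VC": DesignSpec("SI-VC", use_sources=True, include_target_train=False,
                        procrustes=False, vc=True),
    "SI-VC-P": DesignSpec("SI-VC-P", use_sources=True, include_target_train=False,
                          procrustes=True, vc=True),
    "SA-P": DesignSpec("SA-P", use_sources=True, include_target_train=True,
                       procrustes=True, vc=False),
    "SA-VC-P": DesignSpec("SA-VC-P", use_sources=True, include_target_train=True,
                          procrustes=True, vc=True),
}


def design_from_name(name: str) -> DesignSpec:
    if name not in _DESIGNS:
        raise ValueError(f"unknown design {name!r}; choose from {DESIGN_NAMES}")
    return _DESIGNS[name]


def _subseed(seed: int, *keys) -> int:
    codes = [zlib.crc32(str(k).encode()) for k in keys]
    ss = np.random.SeedSequence([int(seed)] + codes)
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Feature preparation (shared across designs/targets)
# ---------------------------------------------------------------------------

Key = tuple[str, str]  # (speaker_id, utt_id)


class PreparedCorpus:
    """Cached acoustic and articulatory features for a split corpus.

    Mel/MFCC are extracted once from audio; articulatory features exist in a
    raw and a Procrustes-matched (sentence-level) variant, both interpolated
    to the utterance's mel frame count and stacked with Δ/ΔΔ.
    """

    def __init__(self, corpora: list[SpeakerCorpus]):
        for c in corpora:
            c.validate_split()
        self.corpora = {c.speaker_id: c for c in corpora}
        self.speakers = sorted(self.corpora)
        self.mel: dict[Key, np.ndarray] = {}
        self.mfcc: dict[Key, np.ndarray] = {}
        for c in corpora:
            for u in c.utterances:
                m = features.mel_spectrogram(u.audio, u.audio_rate)
                self.mel[(c.speaker_id, u.utt_id)] = m
                self.mfcc[(c.speaker_id, u.utt_id)] = features.mfcc_from_mel(m)
        self._artic: dict[bool, dict[Key, np.ndarray]] = {}

    def artic(self, procrustes: bool) -> dict[Key, np.ndarray]:
        if procrustes not in self._artic:
            corpora = list(self.corpora.values())
            if procrustes:
                corpora, _ = match_corpus(corpora, level="sentence")
            table = {}
            for c in corpora:
                for u in c.utterances:
                    key = (c.speaker_id, u.utt_id)
                    table[key] = features.artic_features(u.ema, self.mel[key].shape[0])
            self._artic[procrustes] = table
        return self._artic[procrustes]

    def keys(self, speaker: str, part: str) -> list[Key]:
        return [(speaker, u.utt_id) for u in self.corpora[speaker].subset(part)]


# ---------------------------------------------------------------------------
# Voice conversion
# ---------------------------------------------------------------------------

@dataclass
class VcModel:
    """Per source→target voice-conversion model with its I/O normalisation."""

    source: str
    target: str
    model: TrainedModel
    in_stats: features.NormStats
    out_stats: features.NormStats
    test_mcd: float | None = None

    def convert(self, mel: np.ndarray) -> np.ndarray:
        x = features.zscore_apply(mel, self.in_stats)
        y = predict_sequence(self.model, x)
        return features.zscore_invert(y, self.out_stats)


def build_vc_training_pairs(
    corpora: list[SpeakerCorpus] | PreparedCorpus,
    target_speaker: str,
    seed: int = 0,
    n_val: int = 14,
    n_test: int = 14,
) -> dict[str, dict[str, list[tuple[np.ndarray, np.ndarray]]]]:
    """DTW-aligned (source → target) mel pairs on shared prompts, pre-split.

    For every source speaker, parallel prompts shared with the target are
    aligned (source warped onto the target's time base) and split by seeded
    selection into ``n_val`` validation, ``n_test`` test and the remaining
    training pairs.  A source sharing no prompts with the target aborts with
    an error naming every missing pair.
    """
    prep = corpora if isinstance(corpora, PreparedCorpus) else PreparedCorpus(corpora)
    if target_speaker not in prep.corpora:
        raise ValueError(f"unknown target speaker {target_speaker!r}")
    tgt = prep.corpora[target_speaker]
    tgt_by_prompt = {u.prompt_id: u.utt_id for u in tgt.utterances}
    missing = []
    out: dict[str, dict[str, list]] = {}
    for src_id in prep.speakers:
        if src_id == target_speaker:
            continue  # self-conversion not applicable
        src = prep.corpora[src_id]
        src_by_prompt = {u.prompt_id: u.utt_id for u in src.utterances}
        shared = sorted(set(tgt_by_prompt) & set(src_by_prompt))
        if not shared:
            missing.append((src_id, target_speaker))
            continue
        if n_val + n_test >= len(shared):
            raise ValueError(
                f"pair ({src_id}, {target_speaker}): {len(shared)} shared prompts "
                f"cannot supply {n_val} val + {n_test} test plus training pairs"
            )
        rng = np.random.default_rng(_subseed(seed, "vc-split", src_id, target_speaker))
        order = rng.permutation(len(shared))
        parts: dict[str, list] = {"train": [], "val": [], "test": []}
        for rank, idx in enumerate(order):
            prompt = shared[idx]
            part = "val" if rank < n_val else "test" if rank < n_val + n_test else "train"
            src_mel = prep.mel[(src_id, src_by_prompt[prompt])]
            tgt_mel = prep.mel[(target_speaker, tgt_by_prompt[prompt])]
            path, _ = dtw_align(src_mel, tgt_mel)
            parts[part].append((warp_to_target(src_mel, path), tgt_mel))
        out[src_id] = parts
    if missing:
        raise ValueError(f"no shared prompts for source/target pairs: {missing}")
    return out


def build_vc_models(
    prep: PreparedCorpus,
    target_speaker: str,
    seed: int,
    vc_spec: RegressorSpec | None = None,
    n_val: int = 14,
    n_test: int = 14,
) -> dict[str, VcModel]:
    """Train one BLSTM voice-conversion model per source→target pair."""
    vc_spec = vc_spec or default_spec("vc")
    pairs = build_vc_training_pairs(prep, target_speaker, seed, n_val, n_test)
    out = {}
    for src_id, parts in pairs.items():
        in_stats = features.zscore_fit([x for x, _ in parts["train"]])
        out_stats = features.zscore_fit([y for _, y in parts["train"]])
        norm = lambda lst: [
            (features.zscore_apply(x, in_stats), features.zscore_apply(y, out_stats))
            for x, y in lst
        ]
        model = train_regressor(
            vc_spec, norm(parts["train"]), norm(parts["val"]),
            seed=_subseed(seed, "vc-train", src_id, target_speaker),
        )
        vcm = VcModel(src_id, target_speaker, model, in_stats, out_stats)
        if parts["test"]:
            mcds = [
                mcd(features.mfcc_from_mel(y), features.mfcc_from_mel(vcm.convert(x)))
                for x, y in parts["test"]
            ]
            vcm.test_mcd = float(np.mean(mcds))
        out[src_id] = vcm
    return out


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    design: str
    target_speaker: str
    mcd: float
    per_sentence: dict[str, float]
    seed: int
    train_keys: list[Key]
    model: TrainedModel
    config: dict = field(default_factory=dict)


def run_design(
    corpora: list[SpeakerCorpus] | PreparedCorpus,
    target_speaker: str,
    design: DesignSpec | str,
    seed: int = 0,
    ats_spec: RegressorSpec | None = None,
    vc_spec: RegressorSpec | None = None,
    vc_models: dict[str, VcModel] | None = None,
    n_vc_val: int = 14,
    n_vc_test: int = 14,
) -> ExperimentResult:
    """Run one design for one target speaker and return its test MCD.

    ``vc_models`` may be passed to reuse conversions across designs; they are
    built on demand for VC designs otherwise.
    """
    if isinstance(design, str):
        design = design_from_name(design)
    prep = corpora if isinstance(corpora, PreparedCorpus) else PreparedCorpus(corpora)
    if target_speaker not in prep.corpora:
        raise ValueError(f"unknown target speaker {target_speaker!r}")
    sources = [s for s in prep.speakers if s != target_speaker]

    artic = prep.artic(design.procrustes)

    train_keys: list[Key] = []
    if design.use_sources:
        for s in sources:
            train_keys += prep.keys(s, "train")
    if design.include_target_train:
        train_keys += prep.keys(target_speaker, "train")
    if design.use_sources and not design.include_target_train:
        val_keys = [k for s in sources for k in prep.keys(s, "val")]
    else:
        val_keys = prep.keys(target_speaker, "val")
    test_keys = prep.keys(target_speaker, "test")

    if design.vc:
        if vc_models is None:
            vc_models = build_vc_models(prep, target_speaker, seed, vc_spec,
                                        n_vc_val, n_vc_test)
        def target_mel(key: Key) -> np.ndarray:
            spk = key[0]
            if spk == target_speaker:
                return prep.mel[key]
            return vc_models[spk].convert(prep.mel[key])
    else:
        def target_mel(key: Key) -> np.ndarray:
            return prep.mel[key]

    if design.zscore:
        in_stats = features.zscore_fit([artic[k] for k in train_keys])
        x_of = lambda k: features.zscore_apply(artic[k], in_stats)
    else:
        x_of = lambda k: artic[k]

    train_targets = {k: target_mel(k) for k in train_keys}
    out_stats = features.zscore_fit(list(train_targets.values()))
    pair = lambda k, y: (x_of(k), features.zscore_apply(y, out_stats))
    train_pairs = [pair(k, train_targets[k]) for k in train_keys]
    val_pairs = [pair(k, target_mel(k)) for k in val_keys]

    spec = ats_spec or default_spec("ats_sd" if design.name == "SD" else "ats_si")
    model = train_regressor(
        spec, train_pairs, val_pairs,
        seed=_subseed(seed, "ats-train", design.name, target_speaker),
    )

    per_sentence = {}
    for key in test_keys:
        pred_mel = features.zscore_invert(predict_sequence(model, x_of(key)), out_stats)
        per_sentence[key[1]] = mcd(prep.mfcc[key], features.mfcc_from_mel(pred_mel))
    return ExperimentResult(
        design=design.name, target_speaker=target_speaker,
        mcd=float(np.mean(list(per_sentence.values()))),
        per_sentence=per_sentence, seed=seed, train_keys=train_keys, model=model,
        config={"ats_spec": spec.__dict__, "design": design.__dict__},
    )


def run_all(
    corpora: list[SpeakerCorpus] | PreparedCorpus,
    designs: list[str] | None = None,
    seed: int = 0,
    ats_spec: RegressorSpec | None = None,
    sd_spec: RegressorSpec | None = None,
    vc_spec: RegressorSpec | None = None,
    n_vc_val: int = 14,
    n_vc_test: int = 14,
) -> EvaluationReport:
    """Full leave-one-subject-out loop over designs; returns the MCD report.

    Rows are target speakers (sorted), columns designs; VC models are shared
    across the designs of one target.  ``ats_spec`` overrides the topology
    for non-SD designs, ``sd_spec`` for SD.
    """
    prep = corpora if isinstance(corpora, PreparedCorpus) else PreparedCorpus(corpora)
    if len(prep.speakers) < 2:
        raise ValueError("need at least 2 speakers for cross-validation")
    designs = list(designs) if designs is not None else list(DESIGN_NAMES)
    table = pd.DataFrame(index=prep.speakers, columns=designs, dtype=float)
    vc_cells: dict[str, dict[str, float]] = {}
    for target in prep.speakers:
        vcm = None
        if any(design_from_name(d).vc for d in designs):
            vcm = build_vc_models(prep, target, seed, vc_spec, n_vc_val, n_vc_test)
            vc_cells[target] = {s: m.test_mcd for s, m in vcm.items()
                                if m.test_mcd is not None}
        for name in designs:
            d = design_from_name(name)
            spec = (sd_spec if name == "SD" else ats_spec)
            res = run_design(prep, target, d, seed, ats_spec=spec,
                             vc_models=vcm if d.vc else None,
                             n_vc_val=n_vc_val, n_vc_test=n_vc_test)
            table.loc[target, name] = res.mcd
    vc_table = None
    if vc_cells:
        vc_table = pd.DataFrame(index=prep.speakers, columns=prep.speakers, dtype=float)
        for target, row in vc_cells.items():
            for src, value in row.items():
                vc_table.loc[src, target] = value
    return EvaluationReport(mcd_table=table, vc_table=vc_table)
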