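"""On-disk corpus layout: JSON manifest + per-utterance WAV and EMA CSV.

Layout (all paths relative to the manifest)::

    corpus/
      manifest.json
      <speaker>/<utt_id>.wav      float32 mono WAV
      <speaker>/<utt_id>.csv      EMA trajectory, header TT_x,TT_y,TT_z,...

The manifest records, per speaker, the utterance list (utt_id, prompt_id,
file paths, EMA rate) and optionally a split map.  Audio at a rate other
than 22,050 Hz is resampled on load with a polyphase filter
(``scipy.signal.resample_poly``, Kaiser-windowed sinc).  Short runs of
missing EMA samples (NaN, up to 5 consecutive frames by default) are filled
by linear interpolation at load; longer gaps abort the load naming the
utterance.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .data import AUDIO_RATE, EmaTrajectory, SensorLayout, SpeakerCorpus, Utterance

MAX_NAN_GAP = 5

MANIFEST_NAME = "manifest.json"


class CorpusError(ValueError):
    """Raised for malformed corpora (missing files, bad rates, long NaN gaps)."""


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _interpolate_gaps(samples: np.ndarray, utt_id: str, max_gap: int = MAX_NAN_GAP) -> np.ndarray:
    """Fill NaN runs of length <= max_gap per channel; error on longer runs."""
    out = samples.copy()
    t = np.arange(out.shape[0])
    for c in range(out.shape[1]):
        col = out[:, c]
        bad = ~np.isfinite(col)
        if not bad.any():
            continue
        # longest run of consecutive NaNs
        run, longest = 0, 0
        for b in bad:
            run = run + 1 if b else 0
            longest = max(longest, run)
        if longest > max_gap or bad.all() or bad[0] or bad[-1]:
            raise CorpusError(
                f"utterance {utt_id!r}: NaN gap of {longest} frames in channel {c} "
                f"exceeds the {max_gap}-frame interpolation limit"
            )
        col[bad] = np.interp(t[bad], t[~bad], col[~bad])
    return out


def read_ema_csv(path: Path, layout: SensorLayout, utt_id: str, rate: float) -> EmaTrajectory:
    df = pd.read_csv(path)
    expected = layout.column_names()
    if list(df.columns) != expected:
        raise CorpusError(f"utterance {utt_id!r}: EMA columns {list(df.columns)} != {expected}")
    samples = _interpolate_gaps(df.to_numpy(dtype=np.float64), utt_id)
    return EmaTrajectory(samples=samples, rate=rate, layout=layout)


def read_wav(path: Path, utt_id: str) -> tuple[np.ndarray, int]:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise CorpusError(f"utterance {utt_id!r}: audio must be mono")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return data, int(rate)


def resample_audio(audio: np.ndarray, rate: int, target_rate: int = AUDIO_RATE) -> np.ndarray:
    """Polyphase resampling to the target rate (no-op when rates match)."""
    if rate == target_rate:
        return audio
    g = math.gcd(rate, target_rate)
    return resample_poly(audio, target_rate // g, rate // g)


def load_corpus(manifest_path: str | Path) -> list[SpeakerCorpus]:
    """Load and validate the corpora listed in a JSON manifest.

    Audio is resampled to 22,050 Hz; trajectories are gap-interpolated and
    validated; any problem raises :class:`CorpusError` naming the utterance.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    layout = SensorLayout(
        sensor_names=tuple(manifest.get("sensors", SensorLayout().sensor_names)),
        dims=tuple(manifest.get("dims", SensorLayout().dims)),
    )
    corpora = []
    for spk in manifest["speakers"]:
        utts = []
        for entry in spk["utterances"]:
            utt_id = entry["utt_id"]
            ema_path = root / entry["ema"]
            wav_path = root / entry["audio"]
            for p in (ema_path, wav_path):
                if not p.exists():
                    raise CorpusError(f"utterance {utt_id!r}: missing file {p}")
            ema = read_ema_csv(ema_path, layout, utt_id, float(entry.get("ema_rate", 100.0)))
            audio, rate = read_wav(wav_path, utt_id)
            audio = resample_audio(audio, rate)
            utts.append(Utterance(
                utt_id=utt_id, speaker_id=spk["speaker_id"],
                prompt_id=entry["prompt_id"], ema=ema, audio=audio,
            ))
        corpora.append(SpeakerCorpus(
            speaker_id=spk["speaker_id"], utterances=utts, split=spk.get("split"),
        ))
    return corpora


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_corpus(corpora: list[SpeakerCorpus], out_dir: str | Path,
                 extra: dict | None = None) -> Path:
    """Write corpora in the manifest layout; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    speakers = []
    for corpus in corpora:
        spk_dir = out_dir / corpus.speaker_id
        spk_dir.mkdir(exist_ok=True)
        entries = []
        for u in corpus.utterances:
            ema_rel = f"{corpus.speaker_id}/{u.utt_id}.csv"
            wav_rel = f"{corpus.speaker_id}/{u.utt_id}.wav"
            pd.DataFrame(u.ema.samples, columns=u.ema.layout.column_names()).to_csv(
                out_dir / ema_rel, index=False, float_format="%.10g")
            wavfile.write(out_dir / wav_rel, u.audio_rate, u.audio.astype(np.float32))
            entries.append({
                "utt_id": u.utt_id, "prompt_id": u.prompt_id,
                "ema": ema_rel, "audio": wav_rel, "ema_rate": u.ema.rate,
            })
        spk_entry: dict = {"speaker_id": corpus.speaker_id, "utterances": entries}
        if corpus.split is not None:
            spk_entry["split"] = corpus.split
        speakers.append(spk_entry)
    layout = corpora[0].utterances[0].ema.layout if corpora and corpora[0].utterances else SensorLayout()
    manifest = {
        "sensors": list(layout.sensor_names),
        "dims": list(layout.dims),
        "audio_rate": AUDIO_RATE,
        "speakers": speakers,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / MANIFEST_NAME
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# Splits and summaries
# ---------------------------------------------------------------------------

def make_splits(corpus: SpeakerCorpus, n_test: int = 50, n_val: int = 50,
                seed: int = 0) -> SpeakerCorpus:
    """Assign a deterministic train/val/test split by seeded shuffle.

    Utterance ids are sorted, permuted with a seeded generator, and the first
    ``n_test`` become the test set, the next ``n_val`` the validation set,
    the remainder the training set.
    """
    n = len(corpus.utterances)
    if n_test + n_val >= n:
        raise CorpusError(
            f"{corpus.speaker_id}: {n} utterances cannot supply "
            f"{n_test} test + {n_val} val sentences plus a training set"
        )
    ids = sorted(u.utt_id for u in corpus.utterances)
    order = np.random.default_rng(seed).permutation(len(ids))
    split = {}
    for rank, idx in enumerate(order):
        if rank < n_test:
            part = "test"
        elif rank < n_test + n_val:
            part = "val"
        else:
            part = "train"
        split[ids[idx]] = part
    return SpeakerCorpus(corpus.speaker_id, corpus.utterances, split)


def summarize_counts(counts: dict[str, int],
                     durations_min: dict[str, float] | None = None) -> pd.DataFrame:
    """Phrase-count/duration table with ``Sum.`` and ``Ave.`` rows."""
    rows = {
        spk: {
            "phrases": counts[spk],
            "duration_min": (durations_min or {}).get(spk, float("nan")),
        }
        for spk in counts
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=["phrases", "duration_min"], dtype=float)
    df.loc["Sum."] = df.sum()
    df.loc["Ave."] = df.drop(index="Sum.").mean() if len(df) > 1 else 0.0
    return df


def corpus_summary(corpora: list[SpeakerCorpus]) -> pd.DataFrame:
    """Per-speaker phrase counts and audio duration (minutes) with Sum./Ave. rows."""
    counts = {c.speaker_id: len(c.utterances) for c in corpora}
    durations = {
        c.speaker_id: sum(u.audio_duration for u in c.utterances) / 60.0 for c in corpora
    }
    return summarize_counts(counts, durations)


# ---------------------------------------------------------------------------
# Optional external-dataset adapter
# ---------------------------------------------------------------------------

def import_haskins_mat(path: str | Path, speaker_id: str, utt_id: str,
                       prompt_id: str) -> Utterance:
    """Import one utterance from a Haskins-style MATLAB container.

    Isolated adapter for the public 8-speaker production-rate EMA database;
    expects the per-utterance struct layout with named sensor fields holding
    (time × 3) position arrays and an audio field with its sample rate.  The
    core pipeline never depends on this function.
    """
    from scipy.io import loadmat  # local import: optional path only

    mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    key = next(k for k in mat if not k.startswith("__"))
    rec = mat[key]
    layout = SensorLayout()
    cols = []
    audio = None
    audio_rate = None
    for item in np.atleast_1d(rec):
        name = str(getattr(item, "name", "")).upper()
        if name == "AUDIO":
            audio = np.asarray(item.SIGNAL, dtype=np.float64).ravel()
            audio_rate = int(item.SRATE)
        elif name in layout.sensor_names:
            cols.append((name, np.asarray(item.SIGNAL, dtype=np.float64)[:, :3]))
    if audio is None or audio_rate is None:
        raise CorpusError(f"utterance {utt_id!r}: no audio channel in {path}")
    missing = [s for s in layout.sensor_names if s not in dict(cols)]
    if missing:
        raise CorpusError(f"utterance {utt_id!r}: missing sensors {missing}")
    by_name = dict(cols)
    samples = np.concatenate([by_name[s] for s in layout.sensor_names], axis=1)
    samples = _interpolate_gaps(samples, utt_id)
    ema = EmaTrajectory(samples=samples, rate=100.0, layout=layout)
    return Utterance(
        utt_id=utt_id, speaker_id=speaker_id, prompt_id=prompt_id,
        ema=ema, audio=resample_audio(audio, audio_rate),
    )
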