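"""Dataset expansion (noise injection, clipping) and train/val/test split.

The clinical corpus is imbalanced (600 normal vs 200 abnormal originals).
Expansion rebalances it: each normal original contributes its two clips,
each abnormal original contributes six variants (two clips, their
noise-added versions, and the clean + noise-added full-length recording),
yielding 1,200 recordings per class from the 600/200 input.  The expanded
set is then randomly partitioned 70/10/20 into train/validation/test,
stratified by label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import AudioRecording, derive_seed


class DegenerateInputError(ValueError):
    """Operation undefined for this input (e.g. SNR of digital silence)."""


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of an expanded dataset."""

    train: list[AudioRecording]
    validation: list[AudioRecording]
    test: list[AudioRecording]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [r.id for part in (self.train, self.validation, self.test) for r in part]
        if len(ids) != len(set(ids)):
            raise ValueError("splits share recording ids")

    def counts(self) -> dict[str, int]:
        return {
            "train": len(self.train),
            "validation": len(self.validation),
            "test": len(self.test),
        }


def add_white_noise(rec: AudioRecording, snr_db: float, seed: int) -> AudioRecording:
    """Add Gaussian white noise at a given signal-to-noise ratio.

    The noise is scaled so that 10*log10(P_signal / P_noise) == snr_db.
    Raises :class:`DegenerateInputError` on silent input (SNR undefined).
    """
    if len(rec.samples) == 0:
        raise DegenerateInputError("empty recording")
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    p_signal = float(np.mean(rec.samples.astype(np.float64) ** 2))
    if p_signal == 0.0:
        raise DegenerateInputError("silent input: SNR undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(rec.samples))
    noise *= np.sqrt(p_signal / 10 ** (snr_db / 10)) / max(float(noise.std()), 1e-300)
    out = np.clip(rec.samples.astype(np.float64) + noise, -1.0, 1.0)
    return rec.with_samples(
        out,
        id=f"{rec.id}:noise",
        provenance="noise_augmented",
        parent_id=rec.id,
    )


_CLIP_RANGES = {"clip_3_6": (3.0, 6.0), "clip_18_21": (18.0, 21.0)}


def clip_segments(rec: AudioRecording, seed: int) -> tuple[AudioRecording, AudioRecording]:
    """Extract one short (3-6 s) and one long (18-21 s) contiguous clip.

    Durations are uniform within each range; start offsets are uniform over
    the feasible range.  Requires at least 21 s of audio.
    """
    if rec.duration < 21.0 - 1e-9:
        raise ValueError(f"recording too short to clip: {rec.duration:.2f} s < 21 s")
    rng = np.random.default_rng(seed)
    clips = []
    for provenance, (lo, hi) in _CLIP_RANGES.items():
        d = rng.uniform(lo, min(hi, rec.duration))
        n_clip = int(round(d * rec.rate))
        start = int(rng.integers(0, len(rec.samples) - n_clip + 1))
        clips.append(
            rec.with_samples(
                rec.samples[start : start + n_clip],
                id=f"{rec.id}:{provenance}",
                provenance=provenance,
                parent_id=rec.id,
            )
        )
    return clips[0], clips[1]


def expand_and_balance(
    originals,
    snr_db: float = 20.0,
    seed: int = 0,
) -> list[AudioRecording]:
    """Expand originals into a class-balanced augmented dataset.

    Normal originals yield their 2 clips; abnormal originals yield 6
    variants: both clips, both clips with added noise, and the full-length
    recording clean and with added noise.  With 600 normal / 200 abnormal
    input this produces 1,200 recordings per class.  ``originals`` may be
    any iterable (a generator keeps memory at one original at a time).
    """
    out: list[AudioRecording] = []
    labels_seen = set()
    for i, rec in enumerate(originals):
        labels_seen.add(rec.label)
        s_clip = derive_seed(seed, i, 0)
        short, long_ = clip_segments(rec, s_clip)
        if rec.label == "normal":
            out.extend([short, long_])
        else:
            short_n = add_white_noise(short, snr_db, derive_seed(seed, i, 1))
            long_n = add_white_noise(long_, snr_db, derive_seed(seed, i, 2))
            full = rec.with_samples(rec.samples, id=f"{rec.id}:full", parent_id=rec.id)
            full_n = add_white_noise(rec, snr_db, derive_seed(seed, i, 3))
            short_n = short_n.with_samples(
                short_n.samples,
                id=f"{short.id}:noise",
                provenance="clip_3_6_noise",
                parent_id=rec.id,
            )
            long_n = long_n.with_samples(
                long_n.samples,
                id=f"{long_.id}:noise",
                provenance="clip_18_21_noise",
                parent_id=rec.id,
            )
            out.extend([short, long_, short_n, long_n, full, full_n])
    if not out:
        raise ValueError("no originals supplied")
    if labels_seen != {"normal", "abnormal"}:
        raise ValueError(f"both classes required, saw {sorted(labels_seen)}")
    ids = [r.id for r in out]
    if len(ids) != len(set(ids)):
        raise AssertionError("duplicate augmented ids")
    return out


def _apportion(class_counts: dict[str, int], total: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` items among classes."""
    n = sum(class_counts.values())
    quotas = {c: total * k / n for c, k in class_counts.items()}
    base = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = total - sum(base.values())
    order = sorted(class_counts, key=lambda c: (base[c] - quotas[c], c))
    for c in order[:short]:
        base[c] += 1
    return base


def split_dataset(
    expanded: list[AudioRecording],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    group_by_parent: bool = False,
) -> DatasetSplit:
    """Randomly partition into train/validation/test, stratified by label.

    Overall sizes are floor-rounded from ``ratios`` with the remainder going
    to train; within each split, per-class counts follow largest-remainder
    apportionment, so class imbalance per split is at most 1.  With
    ``group_by_parent`` all variants of one original land in the same split
    (prevents sibling leakage; off by default to mirror split-after-
    augmentation bookkeeping).
    """
    if not expanded:
        raise ValueError("empty dataset")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(expanded)
    n_val = int(np.floor(n * ratios[1]))
    n_test = int(np.floor(n * ratios[2]))

    rng = np.random.default_rng(seed)
    if group_by_parent:
        return _split_grouped(expanded, n_val, n_test, rng, seed)

    by_label: dict[str, list[AudioRecording]] = {}
    for rec in expanded:
        by_label.setdefault(rec.label, []).append(rec)
    class_counts = {c: len(v) for c, v in by_label.items()}
    val_quota = _apportion(class_counts, n_val)
    test_quota = _apportion(class_counts, n_test)

    train: list[AudioRecording] = []
    validation: list[AudioRecording] = []
    test: list[AudioRecording] = []
    for c in sorted(by_label):
        members = by_label[c]
        order = rng.permutation(len(members))
        shuffled = [members[j] for j in order]
        validation.extend(shuffled[: val_quota[c]])
        test.extend(shuffled[val_quota[c] : val_quota[c] + test_quota[c]])
        train.extend(shuffled[val_quota[c] + test_quota[c] :])
    return DatasetSplit(train=train, validation=validation, test=test, seed=seed)


def _split_grouped(expanded, n_val, n_test, rng, seed):
    """Parent-grouped split: greedily fill val/test with whole families."""
    families: dict[str, list[AudioRecording]] = {}
    for rec in expanded:
        families.setdefault(rec.parent_id or rec.id, []).append(rec)
    keys = sorted(families)
    order = rng.permutation(len(keys))
    validation, test, train = [], [], []
    for j in order:
        fam = families[keys[j]]
        if len(validation) + len(fam) <= n_val:
            validation.extend(fam)
        elif len(test) + len(fam) <= n_test:
            test.extend(fam)
        else:
            train.extend(fam)
    return DatasetSplit(train=train, validation=validation, test=test, seed=seed)
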