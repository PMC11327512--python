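"""Pairing, subject-grouped fold assignment, oversampling, and HDF5 storage.

A PairedSample couples one pre-swallow segment with one post-swallow segment
from the same subject (and, when substance metadata is present, the same
substance session): the Cartesian product of a subject's pre x post segments.

Folds are assigned at the subject level — all of a subject's pairs land in
one fold, so no individual ever spans a train/test boundary — and are
label-stratified: within each label, shuffled subjects are dealt round-robin.

Training splits may be balanced by random oversampling (duplicating
minority-label pairs with replacement); test splits are never oversampled.

Store layout: /fold{i}/train and /fold{i}/test groups, each with parallel
``ids``, ``labels``, ``sex``, ``pre_audio`` and ``post_audio`` datasets
(audio as variable-length encoded byte payloads); root attributes record
seed, segment length, rate, codec and bitrate.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np

from .audio import AudioSegment, EncodedClip, RawRecording, encode_clip, standardize_recording

logger = logging.getLogger(__name__)

LABELS = {"normal": 0, "aspiration": 1}


@dataclass
class PairedSample:
    """One (pre segment, post segment, label, subject) training unit."""

    subject_id: str
    label: int
    pre: AudioSegment | EncodedClip
    post: AudioSegment | EncodedClip
    sex: Optional[str] = None
    substance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (normal) or 1 (aspiration)")
        for ref, phase in ((self.pre, "pre"), (self.post, "post")):
            if isinstance(ref, AudioSegment):
                if ref.subject_id != self.subject_id:
                    raise ValueError("pair references span different subjects")
                if ref.phase != phase:
                    raise ValueError(f"{phase} reference has phase {ref.phase!r}")


@dataclass
class FoldPlan:
    """Subject-level fold assignment: every subject in exactly one fold."""

    k: int
    assignment: dict[str, int]
    seed: int

    def subjects_in_fold(self, fold: int) -> set[str]:
        return {s for s, f in self.assignment.items() if f == fold}


def enumerate_pairs(
    segments: Sequence[AudioSegment], within_substance: bool = True
) -> list[PairedSample]:
    """Cartesian product of each subject's pre x post segments.

    With ``within_substance`` (default), segments only pair within the same
    substance session; subjects lacking either phase contribute zero pairs.
    """
    grouped: dict[tuple, dict[str, list[AudioSegment]]] = defaultdict(
        lambda: {"pre": [], "post": []}
    )
    for seg in segments:
        key = (seg.subject_id, seg.substance if within_substance else None)
        grouped[key][seg.phase].append(seg)
    pairs: list[PairedSample] = []
    for (subject_id, substance), phases in grouped.items():
        for pre in phases["pre"]:
            for post in phases["post"]:
                label = LABELS[pre.group_label] if pre.group_label else 0
                pairs.append(
                    PairedSample(
                        subject_id=subject_id,
                        label=label,
                        pre=pre,
                        post=post,
                        sex=pre.sex,
                        substance=substance,
                    )
                )
    return pairs


def assign_folds(
    subjects: Sequence[tuple[str, int]],
    k: int = 10,
    seed: int = 0,
    match_keys: Optional[dict[str, str]] = None,
) -> FoldPlan:
    """Label-stratified round-robin assignment of subjects to k folds.

    With ``match_keys``, subjects sharing a key (e.g. matched case-control
    twins in a synthetic cohort) are assigned as one unit and always land in
    the same fold; units are stratified by their label composition. Without
    it, every subject is its own unit and stratification is per label.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = [s for s, _ in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    rng = np.random.default_rng(seed)
    units: dict[str, list[str]] = defaultdict(list)
    unit_labels: dict[str, list[int]] = defaultdict(list)
    for sid, label in subjects:
        key = match_keys.get(sid, sid) if match_keys else sid
        units[key].append(sid)
        unit_labels[key].append(label)
    strata: dict[tuple, list[str]] = defaultdict(list)
    for key in sorted(units):
        strata[tuple(sorted(unit_labels[key]))].append(key)
    assignment: dict[str, int] = {}
    for composition in sorted(strata):
        keys = strata[composition]
        if len(keys) < k:
            logger.warning(
                "stratum %s has %d units for %d folds; stratification is best-effort",
                composition, len(keys), k,
            )
        order = rng.permutation(len(keys))
        for pos, idx in enumerate(order):
            for sid in units[keys[idx]]:
                assignment[sid] = pos % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def oversample_training(
    pairs: Sequence[PairedSample], seed: int = 0, ratio: float = 1.0
) -> list[PairedSample]:
    """Duplicate minority-label pairs with replacement until the minority
    count reaches ``ratio`` x the majority count (1.0 = exact balance).

    All original pairs are retained. Must only ever be applied to training
    splits. A single-label split is returned unchanged with a warning.
    """
    pairs = list(pairs)
    counts = {0: sum(1 for p in pairs if p.label == 0),
              1: sum(1 for p in pairs if p.label == 1)}
    if counts[0] == 0 or counts[1] == 0:
        logger.warning("split contains a single label; oversampling skipped")
        return pairs
    minority = 0 if counts[0] < counts[1] else 1
    if counts[0] == counts[1]:
        return pairs
    target = int(round(ratio * counts[1 - minority]))
    n_extra = max(0, target - counts[minority])
    pool = [p for p in pairs if p.label == minority]
    rng = np.random.default_rng(seed)
    extras = [pool[i] for i in rng.integers(0, len(pool), size=n_extra)]
    return pairs + extras


def _as_clip(ref: AudioSegment | EncodedClip, codec: str) -> EncodedClip:
    return ref if isinstance(ref, EncodedClip) else encode_clip(ref, codec)


def write_store(
    plan: FoldPlan,
    pairs: Sequence[PairedSample],
    path: str | Path,
    codec: str = "wav",
    oversample: bool = True,
    oversample_ratio: float = 1.0,
    seg_len_s: float = 2.0,
    target_rate: int = 32_000,
    bitrate_kbps: int = 64,
) -> None:
    """Materialize the per-fold train/test splits into an HDF5 store.

    Each fold's test split holds exactly that fold's subjects' pairs; its
    train split holds every other subject's pairs, oversampled when enabled.
    """
    missing = {p.subject_id for p in pairs} - set(plan.assignment)
    if missing:
        raise ValueError(f"pairs reference subjects absent from the plan: {missing}")
    vlen_bytes = h5py.special_dtype(vlen=np.dtype("uint8"))
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = plan.seed
        f.attrs["k"] = plan.k
        f.attrs["seg_len_s"] = seg_len_s
        f.attrs["target_rate"] = target_rate
        f.attrs["codec"] = codec
        f.attrs["bitrate_kbps"] = bitrate_kbps
        for fold in range(plan.k):
            fold_subjects = plan.subjects_in_fold(fold)
            test = [p for p in pairs if p.subject_id in fold_subjects]
            train = [p for p in pairs if p.subject_id not in fold_subjects]
            if oversample:
                train = oversample_training(
                    train, seed=plan.seed * 1000 + fold, ratio=oversample_ratio
                )
            for split_name, split in (("train", train), ("test", test)):
                grp = f.create_group(f"fold{fold}/{split_name}")
                grp.create_dataset(
                    "ids", data=[p.subject_id for p in split], dtype=str_dt
                )
                grp.create_dataset(
                    "labels", data=[p.label for p in split], dtype=np.int8
                )
                grp.create_dataset(
                    "sex", data=[p.sex or "" for p in split], dtype=str_dt
                )
                for side in ("pre", "post"):
                    payloads = [
                        np.frombuffer(
                            _as_clip(getattr(p, side), codec).payload, dtype=np.uint8
                        )
                        for p in split
                    ]
                    ds = grp.create_dataset(
                        f"{side}_audio", shape=(len(split),), dtype=vlen_bytes
                    )
                    for i, payload in enumerate(payloads):
                        ds[i] = payload


def read_store(path: str | Path, fold: int, split: str) -> list[PairedSample]:
    """Read one fold/split back as PairedSamples carrying EncodedClips."""
    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    with h5py.File(path, "r") as f:
        key = f"fold{fold}/{split}"
        if key not in f:
            raise KeyError(f"store has no group {key}")
        grp = f[key]
        codec = f.attrs["codec"]
        rate = int(f.attrs["target_rate"])
        bitrate = int(f.attrs["bitrate_kbps"])
        ids = [s.decode() if isinstance(s, bytes) else s for s in grp["ids"][:]]
        labels = grp["labels"][:]
        sexes = [s.decode() if isinstance(s, bytes) else s for s in grp["sex"][:]]
        out = []
        for i, sid in enumerate(ids):
            clips = {}
            for side in ("pre", "post"):
                clips[side] = EncodedClip(
                    payload=bytes(grp[f"{side}_audio"][i]),
                    codec=codec,
                    sample_rate=rate,
                    bitrate_kbps=bitrate if codec == "mp3" else None,
                    source=f"{sid}/{side}",
                )
            out.append(
                PairedSample(
                    subject_id=sid,
                    label=int(labels[i]),
                    pre=clips["pre"],
                    post=clips["post"],
                    sex=sexes[i] or None,
                )
            )
        return out


def build_store_from_recordings(
    recordings: Sequence[RawRecording],
    path: str | Path,
    k: int = 10,
    seed: int = 0,
    target_rate: int = 32_000,
    seg_len_s: float = 2.0,
    codec: str = "wav",
    oversample: bool = True,
    within_substance: bool = True,
    match_key=None,
) -> tuple[FoldPlan, list[PairedSample]]:
    """Standardize in-memory recordings, pair, fold-split and persist.

    ``match_key`` (subject_id -> key) keeps matched subjects in one fold.
    """
    segments = []
    for rec in recordings:
        segments.extend(standardize_recording(rec, target_rate, seg_len_s))
    pairs = enumerate_pairs(segments, within_substance=within_substance)
    subjects = sorted({(p.subject_id, p.label) for p in pairs})
    match_keys = {s: match_key(s) for s, _ in subjects} if match_key else None
    plan = assign_folds(subjects, k=k, seed=seed, match_keys=match_keys)
    write_store(
        plan, pairs, path,
        codec=codec, oversample=oversample,
        seg_len_s=seg_len_s, target_rate=target_rate,
    )
    return plan, pairs


def store_folds(path: str | Path) -> int:
    with h5py.File(path, "r") as f:
        return int(f.attrs["k"])


def store_attrs(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        return dict(f.attrs)
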