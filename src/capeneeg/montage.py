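"""16-channel 10-20 montage, affected/unaffected relabeling, and the electrode-pair catalog.

Patients with unilateral brain damage have variable lesion sides, so the
analysis replaces left/right electrode labels with affected (A) / unaffected
(U) roles: every region keeps its code (FP, F, AT, C, MT, P, PT, O) and gains
an ``a`` or ``u`` suffix depending on which hemisphere was lesioned.  All
cortical-network features are computed over a fixed catalog of ten
within-hemisphere pairs anchored at the central electrode: six *local* pairs
(C to F, MT, P on each side) and four *remote* pairs (C to FP and O on each
side).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import DataError, MontageError

#: Region codes in canonical anterior-to-posterior order.
REGIONS: tuple[str, ...] = ("FP", "F", "AT", "C", "MT", "P", "PT", "O")

#: Conventional 10-20 physical names for each region's (left, right) pair.
REGION_CHANNELS: dict[str, tuple[str, str]] = {
    "FP": ("Fp1", "Fp2"),
    "F": ("F3", "F4"),
    "AT": ("F7", "F8"),
    "C": ("C3", "C4"),
    "MT": ("T3", "T4"),
    "P": ("P3", "P4"),
    "PT": ("T5", "T6"),
    "O": ("O1", "O2"),
}

#: Canonical channel order: left then right within each region.
CANONICAL_LABELS: tuple[str, ...] = tuple(
    ch for region in REGIONS for ch in REGION_CHANNELS[region]
)

CONDITIONS: tuple[str, ...] = ("closed_eyes", "pain_affected", "pain_unaffected")

Side = Literal["left", "right"]

# 10-20 label normalization: case-insensitive plus legacy temporal synonyms
# (T7/T8 and P7/P8 are the modern names for T3/T4 and T5/T6).
_ALIASES = {"t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6"}
_CANON_BY_LOWER = {lbl.lower(): lbl for lbl in CANONICAL_LABELS}


def normalize_label(label: str) -> str:
    """Map a raw channel label to its canonical 10-20 name.

    Strips common reference suffixes (``-REF``, ``-A1``...), fixes case and
    resolves legacy temporal synonyms.  Raises :class:`MontageError` for
    labels outside the 16-channel montage.
    """
    raw = label.strip()
    key = raw.split("-")[0].strip().lower().replace("eeg ", "")
    key = _ALIASES.get(key, key).lower()
    canon = _CANON_BY_LOWER.get(key) or _CANON_BY_LOWER.get(_ALIASES.get(key, "").lower())
    if canon is None:
        raise MontageError(f"channel label {raw!r} is not in the 16-channel 10-20 montage")
    return canon


@dataclass
class EEGRecording:
    """One condition's multichannel EEG signal.

    Parameters
    ----------
    signal
        Channels x samples array in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered 10-20 names, one per signal row.
    condition
        One of ``closed_eyes``, ``pain_affected``, ``pain_unaffected``.
    patient_id
        Opaque identifier.
    role_labels
        Affected/unaffected role per channel (for example ``Cu``), populated
        by :func:`relabel`.
    """

    signal: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    condition: str
    patient_id: str = ""
    role_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.signal.ndim != 2:
            raise DataError("signal must be a 2-D channels x samples array")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise MontageError(
                f"{len(self.channel_labels)} labels for {self.signal.shape[0]} signal rows"
            )
        validate_montage(self.channel_labels)
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.signal)):
            bad = int(np.count_nonzero(~np.isfinite(self.signal)))
            raise DataError(f"signal contains {bad} non-finite samples")
        if self.condition not in CONDITIONS:
            raise DataError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return the sample vector for a physical or role label."""
        if label in self.channel_labels:
            return self.signal[self.channel_labels.index(label)]
        if self.role_labels and label in self.role_labels:
            return self.signal[self.role_labels.index(label)]
        raise MontageError(f"channel {label!r} not present in recording")


def validate_montage(labels: tuple[str, ...]) -> None:
    """Check that *labels* are exactly the canonical 16-channel set."""
    got = set(labels)
    want = set(CANONICAL_LABELS)
    if got == want and len(labels) == 16:
        return
    missing = sorted(want - got)
    extra = sorted(got - want)
    dups = sorted({l for l in labels if list(labels).count(l) > 1})
    parts = []
    if missing:
        parts.append(f"missing {missing}")
    if extra:
        parts.append(f"unexpected {extra}")
    if dups:
        parts.append(f"duplicated {dups}")
    raise MontageError("invalid montage: " + "; ".join(parts))


def to_canonical_order(
    signal: np.ndarray, labels: tuple[str, ...]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Normalize labels and permute signal rows into canonical order."""
    normed = tuple(normalize_label(l) for l in labels)
    validate_montage(normed)
    order = [normed.index(lbl) for lbl in CANONICAL_LABELS]
    return np.asarray(signal)[order], CANONICAL_LABELS


@dataclass(frozen=True)
class MontageMap:
    """Bijective map from 10-20 labels to affected/unaffected role labels."""

    affected_side: Side
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise ValueError(f"affected_side must be 'left' or 'right', got {self.affected_side!r}")
        if not self.mapping:
            mapping = {}
            for region in REGIONS:
                left, right = REGION_CHANNELS[region]
                left_suffix = "a" if self.affected_side == "left" else "u"
                right_suffix = "u" if self.affected_side == "left" else "a"
                mapping[left] = region + left_suffix
                mapping[right] = region + right_suffix
            object.__setattr__(self, "mapping", mapping)

    def role(self, physical: str) -> str:
        return self.mapping[normalize_label(physical)]

    def physical(self, role: str) -> str:
        inverse = {v: k for k, v in self.mapping.items()}
        return inverse[role]


def relabel(recording: EEGRecording, affected_side: Side) -> EEGRecording:
    """Attach affected/unaffected role labels to a recording.

    The signal matrix is untouched; only ``role_labels`` is populated.  Left
    channels become affected when ``affected_side='left'`` and unaffected
    otherwise, symmetrically for the right.
    """
    montage = MontageMap(affected_side)
    roles = tuple(montage.role(lbl) for lbl in recording.channel_labels)
    return replace(recording, role_labels=roles)


@dataclass(frozen=True)
class ElectrodePair:
    """Directed electrode pair: ``first`` is the template series."""

    first: str
    second: str
    category: Literal["local", "remote"]

    @property
    def name(self) -> str:
        return f"{self.first}-{self.second}"


_LOCAL = [("Cu", "Fu"), ("Cu", "MTu"), ("Cu", "Pu"), ("Ca", "Fa"), ("Ca", "MTa"), ("Ca", "Pa")]
_REMOTE = [("Cu", "FPu"), ("Cu", "Ou"), ("Ca", "FPa"), ("Ca", "Oa")]


def pair_catalog() -> list[ElectrodePair]:
    """The fixed ten-pair catalog: six local and four remote central-anchored pairs.

    Each pair is directed, with the central electrode (Cu or Ca) first; both
    members always share the same affected/unaffected suffix.
    """
    return [ElectrodePair(a, b, "local") for a, b in _LOCAL] + [
        ElectrodePair(a, b, "remote") for a, b in _REMOTE
    ]
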