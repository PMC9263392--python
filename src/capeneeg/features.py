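"""Per-patient C-ApEn feature extraction and the pain-minus-rest difference statistic.

For each of the ten catalog electrode pairs and each recorded condition the
epoch-mean C-ApEn is computed with the central electrode (Cu or Ca) as the
template series.  The prognostic difference statistic is

    D = C-ApEn(Cu-FPu | pain, unaffected side) - C-ApEn(Cu-FPu | closed eyes),

the pain-evoked change in the unaffected central-to-prefrontal network.
Cells whose channels are degenerate (for example a dead electrode) are
recorded as missing, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .capen import CApEnParams, epoch_capen
from .errors import DegenerateSignalError, MissingFeatureError, UndefinedEntropyError
from .montage import EEGRecording, ElectrodePair, MontageMap, pair_catalog

D_PAIR = "Cu-FPu"
D_CONDITIONS = ("pain_unaffected", "closed_eyes")


@dataclass
class PatientFeatures:
    """Pair x condition C-ApEn table for one patient.

    ``capen`` maps ``(pair_name, condition)`` to ``(value, n_epochs)``;
    absent keys are explicitly missing cells.
    """

    patient_id: str
    capen: dict[tuple[str, str], tuple[float, int]] = field(default_factory=dict)
    params: CApEnParams = field(default_factory=CApEnParams)

    def value(self, pair: str, condition: str) -> float:
        try:
            return self.capen[(pair, condition)][0]
        except KeyError:
            raise MissingFeatureError(
                f"patient {self.patient_id}: no C-ApEn for pair {pair} "
                f"under condition {condition!r}"
            ) from None

    @property
    def D(self) -> float:
        """The Cu-FPu pain-minus-rest difference statistic."""
        return difference_statistic(self)


def pair_features(
    recordings: dict[str, EEGRecording],
    montage: MontageMap,
    params: CApEnParams = CApEnParams(),
    pairs: list[ElectrodePair] | None = None,
) -> PatientFeatures:
    """Compute epoch-mean C-ApEn for every catalog pair and available condition.

    Parameters
    ----------
    recordings
        Condition name -> recording; all must share montage and sampling rate.
    montage
        Affected/unaffected role map resolving pair roles to physical channels.
    params
        C-ApEn estimator settings.
    pairs
        Optional catalog subset (defaults to all ten pairs).
    """
    if not recordings:
        raise ValueError("no recordings supplied")
    ids = {rec.patient_id for rec in recordings.values()}
    if len(ids) > 1:
        raise ValueError(f"recordings from multiple patients: {sorted(ids)}")
    fss = {rec.fs for rec in recordings.values()}
    if len(fss) > 1:
        raise ValueError(f"conditions disagree on sampling rate: {sorted(fss)}")
    feats = PatientFeatures(patient_id=next(iter(ids)), params=params)
    for pair in pairs if pairs is not None else pair_catalog():
        first_ch = montage.physical(pair.first)
        second_ch = montage.physical(pair.second)
        for condition, rec in recordings.items():
            try:
                u = rec.channel(first_ch)
                v = rec.channel(second_ch)
                value, n_epochs = epoch_capen(u, v, params)
            except (DegenerateSignalError, UndefinedEntropyError):
                continue  # cell stays missing
            feats.capen[(pair.name, condition)] = (value, n_epochs)
    return feats


def difference_statistic(features: PatientFeatures) -> float:
    """``D = capen(Cu-FPu | pain_unaffected) - capen(Cu-FPu | closed_eyes)``."""
    pain = features.value(D_PAIR, D_CONDITIONS[0])
    rest = features.value(D_PAIR, D_CONDITIONS[1])
    return pain - rest


def features_to_frame(features_list: list[PatientFeatures]) -> pd.DataFrame:
    """Tidy long-format table: patient_id, pair, condition, capen, n_epochs."""
    rows = [
        {
            "patient_id": f.patient_id,
            "pair": pair,
            "condition": condition,
            "capen": value,
            "n_epochs": n_epochs,
        }
        for f in features_list
        for (pair, condition), (value, n_epochs) in sorted(f.capen.items())
    ]
    return pd.DataFrame(rows, columns=["patient_id", "pair", "condition", "capen", "n_epochs"])


def summary_frame(features_list: list[PatientFeatures]) -> pd.DataFrame:
    """Per-patient summary with the difference statistic (NaN where undefined)."""
    rows = []
    for f in features_list:
        try:
            d = difference_statistic(f)
        except MissingFeatureError:
            d = float("nan")
        rows.append({"patient_id": f.patient_id, "D": d})
    return pd.DataFrame(rows, columns=["patient_id", "D"])
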