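"""Channel sets and frequency bands used throughout the package.

All channel names follow the international 10-20 / 10-10 nomenclature.
The 64-channel montage corresponds to a standard research EEG cap; the
32-channel classification order interleaves left-hemisphere, midline and
right-hemisphere electrodes so that spatially adjacent rows of the sample
matrix are adjacent on the scalp within each hemisphere.
"""

from __future__ import annotations

#: 64-electrode cap montage (10-10 extension of the 10-20 system).
MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "M1", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "M2",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
    "AF7", "AF3", "AF4", "AF8",
    "FT7", "FT8", "TP7", "TP8",
)

#: Frontal/central/parietal 32-channel subset in the spatial order fed to
#: the CNN: the left hemisphere column-by-column, then the midline, then
#: the right hemisphere mirrored.
CHANNEL_ORDER_32: tuple[str, ...] = (
    "F5", "FC5", "C5", "CP5", "P5", "P3", "CP3", "C3", "FC3", "F3",
    "F1", "FC1", "C1", "CP1", "P1", "Cz", "FCz",
    "F2", "FC2", "C2", "CP2", "P2", "P4", "CP4", "C4", "FC4", "F4",
    "F6", "FC6", "C6", "CP6", "P6",
)

#: Candidate fatigue-sensitive channels over the parietal lobe.
PARIETAL_CANDIDATES: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")

#: Frontal channels used for rhythm-entropy and phase-locking analysis.
FRONTAL_SET: tuple[str, ...] = ("F3", "F4", "F5", "F1", "F2", "F6")

#: Left-hemisphere sensorimotor region desynchronized by right-hand
#: imagery, and its right-hemisphere mirror for left-hand imagery.
#: Sensorimotor-rhythm suppression is regional, strongest over the
#: hand-knob motor cortex (C3/C4) and spreading over the surrounding
#: fronto-centro-parietal electrodes.
RIGHT_HAND_ERD_REGION: tuple[str, ...] = (
    "C3", "C5", "C1", "CP3", "FC3", "CP5", "FC5", "P3", "F3", "P5", "F5",
)
LEFT_HAND_ERD_REGION: tuple[str, ...] = (
    "C4", "C6", "C2", "CP4", "FC4", "CP6", "FC6", "P4", "F4", "P6", "F6",
)

#: Default theta / alpha / beta band edges in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}

BAND_NAMES: tuple[str, ...] = ("theta", "alpha", "beta")

assert len(set(MONTAGE_64)) == 64
assert len(set(CHANNEL_ORDER_32)) == 32
assert set(CHANNEL_ORDER_32) <= set(MONTAGE_64)
assert set(PARIETAL_CANDIDATES) <= set(MONTAGE_64)
assert set(FRONTAL_SET) <= set(CHANNEL_ORDER_32)
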