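"""Scalp-electrode montage used as the canonical node order.

The default montage is the 62-channel analysis set of an extended 10-20
64-electrode cap: the full cap minus the mastoid references M1/M2, which
carry no cortical signal of their own. All matrices, feature vectors and
rankings in this package follow this order unless a custom montage is
supplied — a single source of truth that prevents silent channel
misalignment between pipeline stages.
"""

from __future__ import annotations

# Extended 10-20 labels (Quick-Cap 64 layout) with M1/M2 removed: 62 channels.
CHANNELS_62: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)

#: Mastoid reference electrodes, dropped on import of real recordings.
REFERENCE_CHANNELS: tuple[str, ...] = ("M1", "M2")

assert len(CHANNELS_62) == 62


def canonical_order(labels: list[str] | tuple[str, ...]) -> list[int]:
    """Return indices that reorder ``labels`` into canonical montage order.

    Reference channels (M1/M2) are silently dropped.  Raises ``ValueError``
    naming any label that is not part of the montage.
    """
    keep = [(lab, i) for i, lab in enumerate(labels)
            if lab.upper() not in REFERENCE_CHANNELS]
    unknown = [lab for lab, _ in keep if lab.upper() not in CHANNELS_62]
    if unknown:
        raise ValueError(f"unknown channel labels: {unknown}")
    pos = {lab: k for k, lab in enumerate(CHANNELS_62)}
    keep.sort(key=lambda t: pos[t[0].upper()])
    return [i for _, i in keep]
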