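"""Canonical modality names, label conventions and shared defaults."""

#: Canonical modality order. The six T1-weighted dynamic contrast phases come
#: first in acquisition order (pre-contrast, early/late arterial, early/late
#: venous, delayed), followed by the T2-weighted series.
MODALITIES = ("T1pre", "T1a1", "T1a2", "T1v1", "T1v2", "T1post", "T2")

#: The T1 contrast phases in temporal order (used by the monotone-enhancement
#: phantom model; T2 is not part of the enhancement ramp).
CONTRAST_PHASES = MODALITIES[:6]

#: Lesion-center coordinates are expressed in this modality's voxel grid.
REFERENCE_MODALITY = "T1post"

LABELS = ("SCN", "MCN")

#: MCN (mucinous) is the positive class: sensitivity is accuracy on MCN.
POSITIVE_LABEL = "MCN"
NEGATIVE_LABEL = "SCN"

#: Decision threshold on p(MCN); exactly 0.5 maps to MCN.
DECISION_THRESHOLD = 0.5

#: Side length (voxels) of the lesion-centred crop after 1 mm resampling.
CROP_SIZE = 80

#: Fill value for out-of-volume regions after [-1, 1] normalization.
PAD_VALUE = -1.0
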