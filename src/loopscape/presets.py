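"""Named residue-group presets.

The ``ctsb-murine`` preset carries the occluding-loop / active-site /
allosteric-pocket residue groups of murine cathepsin B in UniProt numbering
(P10605).  Residue numbers in any preset refer to numbers as written in the
trajectory file; no renumbering is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Distance at or below which the occluding loop counts as closed (Angstrom).
DEFAULT_STATE_THRESHOLD = 16.5

#: Two heavy atoms of different chains closer than this are in contact (Angstrom).
DEFAULT_CONTACT_CUTOFF = 3.3

#: Gas constant in kJ/(mol K).
GAS_CONSTANT_KJ = 0.008314462618

#: Default temperature for Boltzmann inversion (K).
DEFAULT_TEMPERATURE = 300.0


@dataclass(frozen=True)
class ResidueGroupPreset:
    name: str
    loop_residues: frozenset[int]
    active_site_residues: frozenset[int]
    pocket_residues: frozenset[int]
    threshold: float = DEFAULT_STATE_THRESHOLD
    notes: str = ""


CTSB_MURINE = ResidueGroupPreset(
    name="ctsb-murine",
    # occluding loop covering the active-site cleft
    loop_residues=frozenset(range(185, 201)),
    # catalytic triad region: C108, H278, N298
    active_site_residues=frozenset({108, 278, 298}),
    # allosteric pocket residues validated by mutagenesis
    pocket_residues=frozenset({169, 215, 221, 222, 224, 333}),
    threshold=DEFAULT_STATE_THRESHOLD,
    notes="murine cathepsin B, UniProt P10605 numbering",
)

PRESETS: dict[str, ResidueGroupPreset] = {CTSB_MURINE.name: CTSB_MURINE}


def get_preset(name: str) -> ResidueGroupPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
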