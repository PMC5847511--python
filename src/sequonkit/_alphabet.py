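"""Amino-acid alphabet policy shared across the package.

The 20 standard residues are the working alphabet.  The ambiguity codes
X/B/Z/J may appear in input sequences but a window containing any of them
is never asserted to be a sequon.  The rare translated residues U
(selenocysteine) and O (pyrrolysine) are treated as ordinary residues that
simply never match N, S or T.
"""

from __future__ import annotations

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZJ"
RARE_AA = "UO"

ALLOWED_AA = frozenset(STANDARD_AA + AMBIGUOUS_AA + RARE_AA)

#: residues that disqualify the middle (X) slot of a sequon
SLOT2_FORBIDDEN = frozenset("P" + AMBIGUOUS_AA)

# Background amino-acid frequencies of the reviewed human proteome
# (fractions of total residues; normalised at load time).
SWISSPROT_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0593,
    "L": 0.0966, "K": 0.0582, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0660, "T": 0.0535, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
_total = sum(SWISSPROT_AA_FREQUENCIES.values())
SWISSPROT_AA_FREQUENCIES = {k: v / _total for k, v in SWISSPROT_AA_FREQUENCIES.items()}
del _total
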