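"""Grantham distances between amino acids and substitution-severity classes.

The Grantham distance combines three physicochemical residue properties —
atomic composition c, polarity p and molecular volume v — into a single
dissimilarity

    D(i, j) = rho * [alpha*(c_i - c_j)^2 + beta*(p_i - p_j)^2
                     + gamma*(v_i - v_j)^2]^(1/2)

with the property weights fit so that the distance correlates with observed
residue exchangeability, and rho scaling the mean over all 190 unordered
pairs to 100.  Larger distances mark more radical substitutions.

Two routes are exposed: :data:`GRANTHAM_MATRIX` holds the published integer
table (the ground truth used by annotation), and
:func:`grantham_distance_formula` evaluates the formula from the published
constants.  The two agree to within one unit of rounding on every pair
except Asp-Trp, where the original publication prints 181 while the formula
yields 190.6; the published value is kept.
"""

from __future__ import annotations

# Per-residue (composition, polarity, molecular volume), one-letter codes.
AMINO_ACID_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399
RHO = 50.723

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Published integer distance table, upper triangle in _MATRIX_ORDER order.
_MATRIX_ORDER = "SRLPTAVGIFYCHQNKDEMW"
_MATRIX_UPPER = (
    (110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177),
    (102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101),
    (98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61),
    (38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147),
    (58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128),
    (64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148),
    (109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88),
    (135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184),
    (21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61),
    (22, 205, 100, 116, 158, 102, 177, 140, 28, 40),
    (194, 83, 99, 143, 85, 160, 122, 36, 37),
    (174, 154, 139, 202, 154, 170, 196, 215),
    (24, 68, 32, 81, 40, 87, 115),
    (46, 53, 61, 29, 101, 130),
    (94, 23, 42, 142, 174),
    (101, 56, 95, 110),
    (45, 160, 181),
    (126, 152),
    (67,),
)


def _build_matrix() -> dict[tuple[str, str], int]:
    matrix: dict[tuple[str, str], int] = {}
    for i, x in enumerate(_MATRIX_ORDER):
        matrix[(x, x)] = 0
        row = _MATRIX_UPPER[i] if i < len(_MATRIX_UPPER) else ()
        for y, value in zip(_MATRIX_ORDER[i + 1:], row):
            matrix[(x, y)] = value
            matrix[(y, x)] = value
    return matrix


#: Published integer Grantham matrix, symmetric, zero on the diagonal.
GRANTHAM_MATRIX: dict[tuple[str, str], int] = _build_matrix()

#: Severity class upper bounds on the Grantham score (inclusive), in order.
GMS_CLASS_BOUNDARIES: tuple[tuple[str, int], ...] = (
    ("conservative", 50),
    ("moderately conservative", 100),
    ("moderately radical", 150),
)
GMS_RADICAL_CLASS = "radical"

GMS_CLASSES = tuple(name for name, _ in GMS_CLASS_BOUNDARIES) + (GMS_RADICAL_CLASS,)


def _normalize_residue(residue: str) -> str:
    aa = residue.strip().upper()
    if len(aa) == 3:
        aa = _THREE_TO_ONE.get(aa, aa)
    if aa not in AMINO_ACID_PROPERTIES:
        raise ValueError(f"not a standard amino acid: {residue!r}")
    return aa


def grantham_score(aa_from: str, aa_to: str) -> int:
    """Published integer Grantham distance between two residues.

    Accepts one- or three-letter codes; symmetric; 0 only for identical
    residues.
    """
    a = _normalize_residue(aa_from)
    b = _normalize_residue(aa_to)
    return GRANTHAM_MATRIX[(a, b)]


def grantham_distance_formula(aa_from: str, aa_to: str) -> float:
    """Grantham distance evaluated from the physicochemical constants.

    Used as an internal cross-check of :data:`GRANTHAM_MATRIX`; annotation
    uses the published integers.
    """
    a = _normalize_residue(aa_from)
    b = _normalize_residue(aa_to)
    c1, p1, v1 = AMINO_ACID_PROPERTIES[a]
    c2, p2, v2 = AMINO_ACID_PROPERTIES[b]
    ss = ALPHA * (c1 - c2) ** 2 + BETA * (p1 - p2) ** 2 + GAMMA * (v1 - v2) ** 2
    return RHO * ss ** 0.5


def classify_gms(score: int | float) -> str:
    """Map a Grantham score onto the four substitution-severity classes.

    Boundaries: conservative 0-50, moderately conservative 51-100,
    moderately radical 101-150, radical >= 151.
    """
    if score < 0:
        raise ValueError(f"Grantham score must be non-negative, got {score}")
    for name, upper in GMS_CLASS_BOUNDARIES:
        if score <= upper:
            return name
    return GMS_RADICAL_CLASS
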