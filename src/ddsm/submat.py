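"""Amino-acid substitution matrices in the NCBI BLAST text format.

A substitution matrix scores the replacement of one residue by another.
The motif calculus built on top of it (see :mod:`ddsm.core`) needs two
things from a matrix: the raw integer score ``S(x, y)`` and, per residue,
a *conservation probability* — the chance that a residue does not mutate
to any other residue, estimated as the diagonal score's share of all
strictly positive scores in that residue's row:

    P(x) = S(x, x) / sum_{y : S(x, y) > 0} S(x, y)

Residues such as G, C, H, P and W under BLOSUM62, whose only positive
score is the diagonal, have conservation probability exactly 1.

Six matrices used by standalone BLAST are bundled as plain-text files:
BLOSUM45, BLOSUM62, BLOSUM80, PAM30, PAM70 and PAM250.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "STANDARD_ALPHABET",
    "SubstitutionMatrix",
    "MatrixFormatError",
    "parse_matrix",
    "load_matrix",
    "bundled_matrix_names",
    "residue_conservation",
]

#: The 20 standard amino-acid one-letter codes, in NCBI matrix order.
STANDARD_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

_BUNDLED = ("BLOSUM45", "BLOSUM62", "BLOSUM80", "PAM30", "PAM70", "PAM250")


class MatrixFormatError(ValueError):
    """Raised when a matrix file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 integer scoring table over the standard alphabet.

    Scores for ambiguity codes (B, Z, X) and the stop/gap symbol (*) present
    in NCBI files are dropped at parse time; the calculus operates on the
    20-letter alphabet only.
    """

    name: str
    scores: dict[tuple[str, str], int] = field(repr=False)

    @property
    def alphabet(self) -> str:
        return STANDARD_ALPHABET

    def score(self, x: str, y: str) -> int:
        """Return S(x, y), the score of substituting residue y by x."""
        try:
            return self.scores[(x, y)]
        except KeyError:
            raise KeyError(
                f"non-standard residue pair ({x!r}, {y!r}) for {self.name}"
            ) from None

    def __contains__(self, residue: str) -> bool:
        return residue in STANDARD_ALPHABET


def parse_matrix(text: str, name: str = "matrix") -> SubstitutionMatrix:
    """Parse an NCBI BLAST text matrix into a :class:`SubstitutionMatrix`.

    The format is a header row of residue codes followed by one row per
    residue; ``#`` starts a comment. Rows and columns for non-standard
    codes are parsed then discarded. Symmetry over the 20 standard residues
    is enforced.

    Raises
    ------
    MatrixFormatError
        If a standard residue row or column is missing, a row has the wrong
        number of entries, or the table is asymmetric.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise MatrixFormatError("empty matrix file")
    header = lines[0].split()
    if any(len(tok) != 1 for tok in header):
        raise MatrixFormatError(f"malformed header row: {lines[0]!r}")
    col_of = {res: i for i, res in enumerate(header)}
    missing_cols = [r for r in STANDARD_ALPHABET if r not in col_of]
    if missing_cols:
        raise MatrixFormatError(f"missing residue columns: {missing_cols}")

    rows: dict[str, list[int]] = {}
    for ln in lines[1:]:
        toks = ln.split()
        res = toks[0]
        if len(res) != 1:
            raise MatrixFormatError(f"malformed row label in line: {ln!r}")
        try:
            vals = [int(t) for t in toks[1:]]
        except ValueError as exc:
            raise MatrixFormatError(f"non-integer score in row {res}: {exc}") from None
        if len(vals) != len(header):
            raise MatrixFormatError(
                f"row {res} has {len(vals)} scores, expected {len(header)}"
            )
        rows[res] = vals

    missing_rows = [r for r in STANDARD_ALPHABET if r not in rows]
    if missing_rows:
        raise MatrixFormatError(f"missing residue rows: {missing_rows}")

    scores: dict[tuple[str, str], int] = {}
    for x in STANDARD_ALPHABET:
        for y in STANDARD_ALPHABET:
            scores[(x, y)] = rows[x][col_of[y]]
    for x in STANDARD_ALPHABET:
        for y in STANDARD_ALPHABET:
            if scores[(x, y)] != scores[(y, x)]:
                raise MatrixFormatError(
                    f"asymmetric entry S({x},{y})={scores[(x, y)]} "
                    f"vs S({y},{x})={scores[(y, x)]}"
                )
    return SubstitutionMatrix(name=name, scores=scores)


def bundled_matrix_names() -> tuple[str, ...]:
    """Names of the matrices shipped with the package."""
    return _BUNDLED


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load a bundled matrix by name (case-insensitive), e.g. ``"BLOSUM62"``."""
    key = name.upper().replace(" ", "")
    if key not in _BUNDLED:
        raise KeyError(f"unknown matrix {name!r}; bundled: {', '.join(_BUNDLED)}")
    text = resources.files("ddsm.matrices").joinpath(f"{key}.txt").read_text()
    return parse_matrix(text, name=key)


def residue_conservation(m: SubstitutionMatrix, x: str) -> float:
    """Probability that residue ``x`` is conserved rather than substituted.

    Computed as the diagonal score divided by the sum of the strictly
    positive scores in x's row. Always in (0, 1]; equals 1 exactly when the
    diagonal is the row's only strictly positive entry.
    """
    if len(x) != 1 or x not in STANDARD_ALPHABET:
        raise ValueError(f"non-standard residue {x!r}")
    diag = m.score(x, x)
    if diag <= 0:
        raise ValueError(f"S({x},{x}) = {diag} is not positive in {m.name}")
    positive_total = sum(s for y in STANDARD_ALPHABET if (s := m.score(x, y)) > 0)
    return diag / positive_total
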