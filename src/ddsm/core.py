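"""The DDSM motif calculus.

Motifs (short residue strings) extracted from protein families are often
near-duplicates of one another: positions mutate to chemically similar
residues without changing structure or function. This module quantifies
that redundancy with a substitution matrix and collapses a motif set into
clusters, each represented by a single *main motif*.

Definitions, for a matrix with scores ``S(x, y)`` and per-residue
conservation probabilities ``P(x)`` (see :func:`ddsm.submat.residue_conservation`):

* mutation probability of a motif M of length k:
  ``P_m(M) = 1 - prod_{i=1..k} P(M[i])``
* motif substitution score: ``S_m(X, Y) = sum_i S(X[i], Y[i])``
* substitution probability of M' by M: ``SP(M, M') = S_m(M, M') / S_m(M, M)``
  (the best substitute of M is M itself, so SP(M, M) = 1)

M *can substitute* M' when the motifs have equal length, every positionwise
score ``S(M[i], M'[i])`` is >= 0, and ``SP(M, M') >= T`` for a user
threshold T in [0, 1].

Clustering assigns each motif M' to the candidate substitute with the
highest mutation probability (the candidate set always contains M' itself);
filtering keeps only the distinct main motifs, in sorted order. Every
removed motif remains substitutable by its retained main motif, so the
reduced feature set carries the same information once presence marking
accepts substitutes (see :func:`ddsm.context.build_context`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .submat import STANDARD_ALPHABET, SubstitutionMatrix, residue_conservation

__all__ = [
    "validate_motif",
    "motif_mutation_prob",
    "motif_substitution_score",
    "substitution_prob",
    "can_substitute",
    "MotifClustering",
    "cluster_motifs",
    "filter_main_motifs",
    "truncate",
]

_STANDARD = frozenset(STANDARD_ALPHABET)


def validate_motif(motif: str) -> str:
    """Check that ``motif`` is a non-empty string over the standard alphabet."""
    if not motif:
        raise ValueError("empty motif")
    bad = set(motif) - _STANDARD
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in motif {motif!r}")
    return motif


def truncate(value: float, decimals: int = 2) -> float:
    """Truncate (floor toward zero) to the given number of decimals.

    Used when comparing probabilities at printed precision: 0.87654 prints
    as 0.87, which rounding would turn into 0.88.
    """
    factor = 10**decimals
    return math.floor(value * factor) / factor


def motif_mutation_prob(motif: str, m: SubstitutionMatrix) -> float:
    """Probability P_m that the motif mutates to some other motif.

    One minus the product of the per-residue conservation probabilities.
    Lies in [0, 1); zero exactly when every residue's only positive score
    is its diagonal (e.g. any motif over G, C, H, P, W under BLOSUM62).
    """
    validate_motif(motif)
    prod = 1.0
    for x in motif:
        prod *= residue_conservation(m, x)
    return 1.0 - prod


def motif_substitution_score(x: str, y: str, m: SubstitutionMatrix) -> int:
    """Positionwise substitution score S_m(X, Y) of motif Y by motif X."""
    validate_motif(x)
    validate_motif(y)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {x!r} vs {y!r}")
    return sum(m.score(a, b) for a, b in zip(x, y))


def substitution_prob(motif: str, other: str, m: SubstitutionMatrix) -> float:
    """Substitution probability SP(M, M') = S_m(M, M') / S_m(M, M).

    SP(M, M) is exactly 1; under the positionwise non-negativity condition
    the value lies in [0, 1] for the bundled matrices.
    """
    return motif_substitution_score(motif, other, m) / motif_substitution_score(
        motif, motif, m
    )


def can_substitute(motif: str, other: str, m: SubstitutionMatrix, t: float) -> bool:
    """Whether motif M can substitute motif M' at threshold ``t``.

    True iff (1) equal lengths, (2) S(M[i], M'[i]) >= 0 at every position,
    and (3) SP(M, M') >= t. A length mismatch returns False rather than
    raising: unequal lengths simply fail condition 1.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold T={t} outside [0, 1]")
    validate_motif(motif)
    validate_motif(other)
    if len(motif) != len(other):
        return False
    if any(m.score(a, b) < 0 for a, b in zip(motif, other)):
        return False
    return substitution_prob(motif, other, m) >= t


def sort_motifs(motifs, m: SubstitutionMatrix) -> list[str]:
    """Sort descending by length, then by P_m, ties broken lexicographically."""
    return sorted(set(motifs), key=lambda M: (-len(M), -motif_mutation_prob(M, m), M))


@dataclass(frozen=True)
class MotifClustering:
    """Result of clustering a motif set under a matrix and threshold T.

    ``main_of`` maps every input motif to its main motif; ``clusters`` maps
    each main motif to its member set (the main motif is always a member of
    its own cluster, so a motif absorbed by another cluster but heading its
    own appears in both — it is then the main of one of them).
    """

    main_of: dict[str, str]
    clusters: dict[str, frozenset[str]]
    p_m: dict[str, float]
    matrix_name: str
    threshold: float

    @property
    def main_motifs(self) -> set[str]:
        return set(self.clusters)

    def to_table(self) -> str:
        """Two-column TSV (motif, main motif), motifs in sorted input order."""
        lines = ["motif\tmain_motif"]
        lines += [f"{motif}\t{main}" for motif, main in self.main_of.items()]
        return "\n".join(lines) + "\n"


def cluster_motifs(motifs, m: SubstitutionMatrix, t: float) -> MotifClustering:
    """Assign every motif to the substituting motif with the highest P_m.

    Motifs are first sorted descending by length then P_m (ties broken
    lexicographically). For each motif M', the main motif is the candidate
    M among the inputs with ``can_substitute(M, M', t)`` that has the
    highest P_m, ties again resolved toward the lexicographically smaller
    motif. M' always substitutes itself, so the assignment is total.
    """
    motifs = list(motifs)
    if not motifs:
        raise ValueError("empty motif set")
    order = sort_motifs(motifs, m)
    pm = {M: motif_mutation_prob(M, m) for M in order}

    main_of: dict[str, str] = {}
    for target in order:
        candidates = [M for M in order if can_substitute(M, target, m, t)]
        main_of[target] = max(candidates, key=lambda M: (pm[M], _lex_desc(M)))

    clusters: dict[str, set[str]] = {}
    for main in main_of.values():
        clusters.setdefault(main, set()).add(main)
    for motif, main in main_of.items():
        clusters[main].add(motif)
    return MotifClustering(
        main_of=main_of,
        clusters={k: frozenset(v) for k, v in clusters.items()},
        p_m=pm,
        matrix_name=m.name,
        threshold=t,
    )


class _lex_desc(str):
    """Inverts lexicographic order so max() prefers the smaller string."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def filter_main_motifs(clustering: MotifClustering) -> list[str]:
    """Retain only the main motifs, in sorted order (length desc, P_m desc).

    This is the filtering step: substitutable motifs are dropped and each
    cluster is represented by its main motif alone. The result never has
    more motifs than the input set.
    """
    pm = clustering.p_m
    mains = set(clustering.main_of.values())
    return sorted(mains, key=lambda M: (-len(M), -pm[M], M))
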