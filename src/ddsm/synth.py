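"""Synthetic multi-family sequence sets with implanted motifs.

Real benchmark sets for family classification consist of distinct protein
families, each carrying preserved family-specific patterns. The generator
emulates that structure: every family gets one or more implanted motifs
placed into otherwise random residue background, and a configurable
fraction of implants is replaced by *variants* — motifs derived by
sampling substitutions with non-negative scores that keep the variant
substitutable by the original (equal length, positionwise scores >= 0,
substitution probability >= T).

With variant rate 0 the discriminative-descriptor pipeline recovers each
implanted motif (or a substring of it); with a positive rate the variants
collapse back onto the original under substitution-matrix clustering,
which is the redundancy the main-motif reduction removes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import substitution_prob, validate_motif
from .extractors import LabeledSequenceSet
from .submat import STANDARD_ALPHABET, SubstitutionMatrix, load_matrix

__all__ = ["FixtureTruth", "generate_fixture"]


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth for a generated fixture."""

    implanted: dict[str, tuple[str, ...]]  # family -> implanted motifs
    variants: dict[str, tuple[tuple[str, str], ...]]  # family -> (motif, variant)


def _positive_substitutes(x: str, m: SubstitutionMatrix) -> list[str]:
    """Residues y != x with S(x, y) >= 0 (condition-2-compatible swaps)."""
    return [y for y in STANDARD_ALPHABET if y != x and m.score(x, y) >= 0]


def sample_variant(
    motif: str,
    m: SubstitutionMatrix,
    t: float,
    rng: random.Random,
    max_tries: int = 200,
) -> str:
    """Sample a variant M' != M with can_substitute(M, M', T) true.

    Substitutions are drawn position by position from the residues with
    non-negative score against the original; candidates failing the
    substitution-probability threshold are rejected and resampled. Raises
    if no qualifying variant exists (e.g. a motif of fully conserved
    residues at a high T, where any change drops SP below threshold).
    """
    validate_motif(motif)
    options = [_positive_substitutes(x, m) for x in motif]
    if all(not opts for opts in options):
        raise ValueError(
            f"motif {motif!r} admits no substitutions with non-negative score"
        )
    for _ in range(max_tries):
        variant = list(motif)
        swappable = [i for i, opts in enumerate(options) if opts]
        n_swaps = rng.randint(1, len(swappable))
        for i in rng.sample(swappable, n_swaps):
            variant[i] = rng.choice(options[i])
        cand = "".join(variant)
        if cand != motif and substitution_prob(motif, cand, m) >= t:
            return cand
    raise ValueError(
        f"no variant of {motif!r} satisfies the substitution conditions at T={t}"
    )


def _random_background(length: int, rng: random.Random, forbidden: list[str]) -> str:
    """Random residue string containing none of the forbidden motifs."""
    for _ in range(1000):
        seq = "".join(rng.choice(STANDARD_ALPHABET) for _ in range(length))
        if not any(f in seq for f in forbidden):
            return seq
    raise RuntimeError("could not generate background avoiding implanted motifs")


def _random_motif(length: int, m: SubstitutionMatrix, rng: random.Random) -> str:
    # prefer motifs with at least one substitutable position so variants exist
    for _ in range(100):
        motif = "".join(rng.choice(STANDARD_ALPHABET) for _ in range(length))
        if any(_positive_substitutes(x, m) for x in motif):
            return motif
    return motif


def generate_fixture(
    families: int = 2,
    per_family: int = 5,
    motifs_per_family: int = 1,
    motif_length: int = 6,
    seq_length: int = 60,
    variant_rate: float = 0.0,
    variants_per_motif: int = 2,
    matrix: SubstitutionMatrix | None = None,
    t: float = 0.9,
    seed: int = 0,
) -> tuple[LabeledSequenceSet, FixtureTruth]:
    """Generate a labeled multi-family set with implanted motifs.

    Each family F_i receives ``motifs_per_family`` random motifs; every
    sequence of the family carries each motif at a random position. A
    fraction ``variant_rate`` of the implants is replaced by a variant
    drawn from a small per-motif pool (``variants_per_motif`` substitutable
    variants sampled once per motif), mirroring how a substituted form of
    a conserved pattern recurs across a family's members rather than being
    unique to one sequence. Background residues are uniform over the
    standard alphabet and are rejected if they contain any family's
    implanted motif, so implants are family-exclusive by construction.
    Fully deterministic for a fixed seed.
    """
    if families < 1 or per_family < 1:
        raise ValueError("families and per_family must be >= 1")
    if not 0 <= variant_rate <= 1:
        raise ValueError("variant_rate must lie in [0, 1]")
    m = matrix if matrix is not None else load_matrix("BLOSUM62")
    rng = random.Random(seed)

    implanted: dict[str, tuple[str, ...]] = {}
    for fi in range(families):
        fam = f"F{fi + 1}"
        implanted[fam] = tuple(
            _random_motif(motif_length, m, rng) for _ in range(motifs_per_family)
        )
    all_motifs = [mo for mos in implanted.values() for mo in mos]

    # one small variant pool per motif, sampled up front, so variants recur
    pools: dict[str, list[str]] = {}
    if variant_rate > 0:
        for motif in all_motifs:
            pool: list[str] = []
            for _ in range(max(1, variants_per_motif)):
                var = sample_variant(motif, m, t, rng)
                if var not in pool:
                    pool.append(var)
            pools[motif] = pool

    records: list[tuple[str, str, str]] = []
    variants: dict[str, list[tuple[str, str]]] = {fam: [] for fam in implanted}
    for fam, motifs in implanted.items():
        block = seq_length // max(len(motifs), 1)
        if block < motif_length:
            raise ValueError("seq_length too small for the requested implants")
        for si in range(per_family):
            seq = _random_background(seq_length, rng, all_motifs)
            # one implant per disjoint block so implants never overwrite each other
            for mi, motif in enumerate(motifs):
                insert = motif
                if variant_rate > 0 and rng.random() < variant_rate:
                    insert = rng.choice(pools[motif])
                    variants[fam].append((motif, insert))
                lo = mi * block
                pos = rng.randrange(lo, lo + block - len(insert) + 1)
                seq = seq[:pos] + insert + seq[pos + len(insert):]
            records.append((f"{fam}_s{si + 1}", seq, fam))

    truth = FixtureTruth(
        implanted=implanted,
        variants={fam: tuple(v) for fam, v in variants.items()},
    )
    return LabeledSequenceSet.from_records(records), truth
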