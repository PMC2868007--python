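"""Feature construction from labeled protein sequence sets.

Four encoders turn a set of sequences partitioned into families into a
list of motif features:

* N-grams — every distinct length-N window;
* amino-acid composition (AAC) — per-sequence residue frequencies rather
  than motifs;
* Active Motifs — substrings of at least a minimum length occurring, up to
  an allowed number of Hamming mismatches, in a minimum fraction of the
  sequences;
* Discriminative Descriptors (DD) — family repeats filtered for
  discrimination (frequent within one family, rare outside it) and
  minimality;
* DDSM — DD features collapsed into substitution-matrix clusters, keeping
  one main motif per cluster (see :mod:`ddsm.core`).

Characters outside the 20 standard residues (B, Z, X, U, *, ...) act as
motif separators: no extracted motif, window or match may span one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import core
from .submat import STANDARD_ALPHABET, SubstitutionMatrix

__all__ = [
    "LabeledSequenceSet",
    "FeatureSet",
    "TooManyFeaturesError",
    "segments",
    "extract_ngrams",
    "amino_acid_composition",
    "extract_active_motifs",
    "extract_repeats",
    "dd_filter",
    "extract_ddsm",
]

_STANDARD = frozenset(STANDARD_ALPHABET)

#: Default cap on generated features; exceeding it raises TooManyFeaturesError.
DEFAULT_FEATURE_CAP = 200_000


class TooManyFeaturesError(RuntimeError):
    """Raised when an encoder would generate more features than the cap."""


@dataclass(frozen=True)
class LabeledSequenceSet:
    """n sequences partitioned into families F_1..F_P.

    ``sequences`` is a list of (id, residues, family) triples; residues are
    uppercased, and any non-standard characters are retained verbatim but
    treated as separators by every extractor.
    """

    sequences: tuple[tuple[str, str, str], ...]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty sequence set")
        ids = [sid for sid, _, _ in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate sequence ids: {dupes}")

    @classmethod
    def from_records(cls, records) -> "LabeledSequenceSet":
        return cls(tuple((sid, seq.upper(), fam) for sid, seq, fam in records))

    @property
    def families(self) -> dict[str, int]:
        """Family label -> member count, in first-seen order."""
        counts: dict[str, int] = {}
        for _, _, fam in self.sequences:
            counts[fam] = counts.get(fam, 0) + 1
        return counts

    def family_sequences(self, family: str) -> list[str]:
        return [seq for _, seq, fam in self.sequences if fam == family]

    @property
    def labels(self) -> list[str]:
        return [fam for _, _, fam in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class FeatureSet:
    """An ordered, distinct list of motif features plus provenance."""

    method: str
    features: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features")

    def __len__(self) -> int:
        return len(self.features)

    def to_text(self) -> str:
        """One motif per line with a '# method/params' header."""
        params = " ".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return "\n".join([f"# {self.method} {params}".rstrip(), *self.features]) + "\n"


def segments(sequence: str) -> list[str]:
    """Split a sequence at non-standard residues into standard-only runs."""
    runs, current = [], []
    for ch in sequence:
        if ch in _STANDARD:
            current.append(ch)
        elif current:
            runs.append("".join(current))
            current = []
    if current:
        runs.append("".join(current))
    return runs


def _ordered_features(motifs) -> tuple[str, ...]:
    """Deterministic feature order: longest first, then lexicographic."""
    return tuple(sorted(set(motifs), key=lambda m: (-len(m), m)))


def extract_ngrams(s: LabeledSequenceSet, n: int) -> FeatureSet:
    """All distinct length-``n`` windows over all sequences.

    Windows containing a non-standard character are skipped (separator
    rule). If no sequence admits a window the feature set is empty.
    """
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    grams: set[str] = set()
    for _, seq, _ in s.sequences:
        for run in segments(seq):
            for i in range(len(run) - n + 1):
                grams.add(run[i : i + n])
    return FeatureSet("NG", _ordered_features(grams), {"N": n})


def amino_acid_composition(sequence: str) -> np.ndarray:
    """Frequency of each of the 20 standard residues in one protein.

    Non-standard characters are ignored; the 20 frequencies sum to 1.
    Order follows :data:`ddsm.submat.STANDARD_ALPHABET`.
    """
    seq = sequence.upper()
    counts = Counter(ch for ch in seq if ch in _STANDARD)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no standard residues")
    return np.array([counts[a] / total for a in STANDARD_ALPHABET])


def _hamming_matches(motif: str, run: str, mutations: int) -> bool:
    k = len(motif)
    for i in range(len(run) - k + 1):
        mismatches = 0
        for a, b in zip(motif, run[i : i + k]):
            if a != b:
                mismatches += 1
                if mismatches > mutations:
                    break
        else:
            return True
    return False


def _activity(motif: str, s: LabeledSequenceSet, mutations: int) -> int:
    """Number of sequences containing a match within <= mutations substitutions."""
    count = 0
    for _, seq, _ in s.sequences:
        if mutations == 0:
            hit = any(motif in run for run in segments(seq))
        else:
            hit = any(_hamming_matches(motif, run, mutations) for run in segments(seq))
        if hit:
            count += 1
    return count


def extract_active_motifs(
    s: LabeledSequenceSet,
    min_length: int = 3,
    activity_pct: float = 25.0,
    mutations: int = 0,
    feature_cap: int = DEFAULT_FEATURE_CAP,
) -> FeatureSet:
    """Substrings of length >= ``min_length`` active in enough sequences.

    A motif's activity is the number of sequences containing a match within
    ``mutations`` Hamming substitutions (no indels); it must reach
    ``activity_pct`` percent of the sequence count. Candidates are the
    observed substrings of the input sequences. The output is capped: on
    combinatorial blow-up a :class:`TooManyFeaturesError` is raised rather
    than silently truncating.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if not 0 < activity_pct <= 100:
        raise ValueError("activity_pct must be in (0, 100]")
    if mutations < 0:
        raise ValueError("mutations must be >= 0")
    required = activity_pct / 100.0 * len(s)

    candidates: set[str] = set()
    for _, seq, _ in s.sequences:
        for run in segments(seq):
            for length in range(min_length, len(run) + 1):
                for i in range(len(run) - length + 1):
                    candidates.add(run[i : i + length])
        if len(candidates) > feature_cap:
            raise TooManyFeaturesError(
                f"active-motif candidates exceed cap ({feature_cap}): "
                "too many attributes"
            )

    active = [m for m in candidates if _activity(m, s, mutations) >= required]
    if len(active) > feature_cap:
        raise TooManyFeaturesError(
            f"active motifs exceed cap ({feature_cap}): too many attributes"
        )
    return FeatureSet(
        "AM",
        _ordered_features(active),
        {"min_length": min_length, "activity_pct": activity_pct, "mutations": mutations},
    )


def extract_repeats(
    family: list[str], min_length: int = 3, max_length: int = 10
) -> set[str]:
    """Repeated substrings within one family.

    A motif is a repeat when it occurs in at least two distinct sequences
    of the family; for a single-sequence family, when it occurs at least
    twice in that sequence. Lengths are restricted to
    [``min_length``, ``max_length``]. Candidates grow length by length:
    every substring of a repeat is itself a repeat, so length l+1
    candidates are one-character extensions of length-l repeats.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if max_length < min_length:
        return set()
    runs_per_seq = [segments(seq) for seq in family]
    single = len(family) == 1

    def occurrences(length: int, seeds: set[str] | None) -> dict[str, object]:
        found: dict[str, object] = {}
        for si, runs in enumerate(runs_per_seq):
            for run in runs:
                for i in range(len(run) - length + 1):
                    sub = run[i : i + length]
                    if seeds is not None and sub[:-1] not in seeds:
                        continue
                    if single:
                        found.setdefault(sub, 0)
                        found[sub] += 1
                    else:
                        found.setdefault(sub, set()).add(si)
        return found

    def is_repeat(support) -> bool:
        return (support >= 2) if single else (len(support) >= 2)

    repeats: set[str] = set()
    # seed at length 1 for pruning, emit only lengths >= min_length
    prev = {m for m, sup in occurrences(1, None).items() if is_repeat(sup)}
    length = 1
    while prev and length < max_length:
        length += 1
        current = {m for m, sup in occurrences(length, prev).items() if is_repeat(sup)}
        if length >= min_length:
            repeats |= current
        prev = current
    if min_length == 1:
        first = {m for m, sup in occurrences(1, None).items() if is_repeat(sup)}
        repeats |= first
    return repeats


def _containment_rate(motif: str, sequences: list[str]) -> float:
    hits = sum(1 for seq in sequences if any(motif in run for run in segments(seq)))
    return hits / len(sequences)


def dd_filter(
    repeats_by_family: dict[str, set[str]],
    s: LabeledSequenceSet,
    alpha: float = 0.0,
    beta: float = 0.0,
) -> FeatureSet:
    """Keep the discriminative, minimal repeats: the DD feature set.

    A motif X is discriminative for family F_i when its containment rate in
    F_i is >= ``alpha`` and its rate in every other family is <= ``beta``.
    Minimality then prunes X if a proper substring of X is also retained
    for the same family. The union over families is deduplicated and
    returned in deterministic order.
    """
    if not 0 <= alpha <= 1 or not 0 <= beta <= 1:
        raise ValueError("alpha and beta must lie in [0, 1]")
    family_seqs = {fam: s.family_sequences(fam) for fam in s.families}

    retained_by_family: dict[str, set[str]] = {}
    for fam, repeats in repeats_by_family.items():
        keep: set[str] = set()
        for motif in repeats:
            if _containment_rate(motif, family_seqs[fam]) < alpha:
                continue
            if beta < 1 and any(
                _containment_rate(motif, seqs) > beta
                for other, seqs in family_seqs.items()
                if other != fam
            ):
                continue
            keep.add(motif)
        retained_by_family[fam] = keep

    minimal: set[str] = set()
    for fam, keep in retained_by_family.items():
        for motif in keep:
            has_retained_substring = any(
                other != motif and other in motif for other in keep
            )
            if not has_retained_substring:
                minimal.add(motif)
    return FeatureSet(
        "DD", _ordered_features(minimal), {"alpha": alpha, "beta": beta}
    )


def extract_dd(
    s: LabeledSequenceSet,
    alpha: float = 0.0,
    beta: float = 0.0,
    min_length: int = 3,
    max_length: int = 10,
) -> FeatureSet:
    """Repeat extraction per family followed by DD filtering."""
    repeats = {
        fam: extract_repeats(s.family_sequences(fam), min_length, max_length)
        for fam in s.families
    }
    return dd_filter(repeats, s, alpha, beta)


def extract_ddsm(
    s: LabeledSequenceSet,
    alpha: float = 0.0,
    beta: float = 0.0,
    m: SubstitutionMatrix | None = None,
    t: float = 0.9,
    min_length: int = 3,
    max_length: int = 10,
) -> FeatureSet:
    """DD features collapsed into main-motif clusters.

    Runs the DD pipeline, clusters its output under the substitution
    matrix at threshold ``t`` and keeps one main motif per cluster. The
    result never has more features than the DD set it came from.
    """
    if m is None:
        from .submat import load_matrix

        m = load_matrix("BLOSUM62")
    dd = extract_dd(s, alpha, beta, min_length, max_length)
    if not dd.features:
        return FeatureSet("DDSM", (), {**dd.params, "matrix": m.name, "T": t})
    clustering = core.cluster_motifs(dd.features, m, t)
    mains = core.filter_main_motifs(clustering)
    return FeatureSet(
        "DDSM",
        tuple(mains),
        {**dd.params, "matrix": m.name, "T": t},
    )
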