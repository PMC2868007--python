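"""Binary learning/test contexts and their serialisation.

A *learning context* is the sequences x features 0/1 table handed to a
classifier: cell (s, f) is 1 when feature motif f is present in sequence
s. Presence is either exact substring occurrence or *substitute-aware*:
the cell is 1 when some window of the sequence (same length as the motif,
not spanning a non-standard residue) can be substituted by the motif
under the matrix and threshold in force. Substitute-aware marking is what
lets a reduced main-motif feature set represent the motifs it absorbed.

A test context must reuse the learning context's feature list unchanged
so that columns align; :func:`build_context` takes the frozen feature
set and ignores whatever motifs the test sequences might have produced.

Writers cover the ARFF format (WEKA dialect, features as nominal {0,1}
attributes with the class last) and RFC-4180 CSV.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np

from .core import can_substitute
from .extractors import FeatureSet, LabeledSequenceSet, segments
from .submat import SubstitutionMatrix

__all__ = ["BinaryContext", "build_context", "write_arff", "write_csv", "read_csv"]


@dataclass(frozen=True)
class BinaryContext:
    """Instances x features 0/1 table with ids and class labels."""

    feature_names: tuple[str, ...]
    ids: tuple[str, ...]
    labels: tuple[str, ...]
    matrix: np.ndarray  # shape (n_instances, n_features), dtype uint8

    def __post_init__(self):
        n, p = self.matrix.shape
        if n != len(self.ids) or n != len(self.labels):
            raise ValueError("row count mismatch between matrix, ids and labels")
        if p != len(self.feature_names):
            raise ValueError("column count mismatch with feature names")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("context entries must be 0 or 1")


def _present_exact(feature: str, runs: list[str]) -> bool:
    return any(feature in run for run in runs)


def _present_substitute(
    feature: str, runs: list[str], m: SubstitutionMatrix, t: float
) -> bool:
    k = len(feature)
    for run in runs:
        for i in range(len(run) - k + 1):
            if can_substitute(feature, run[i : i + k], m, t):
                return True
    return False


def build_context(
    s: LabeledSequenceSet,
    f: FeatureSet,
    mode: str = "exact",
    m: SubstitutionMatrix | None = None,
    t: float | None = None,
) -> BinaryContext:
    """Mark presence (1) or absence (0) of every feature in every sequence.

    ``mode="exact"`` requires the feature as a literal substring;
    ``mode="substitute_aware"`` also accepts any same-length window the
    feature can substitute (conditions: positionwise scores >= 0 and
    substitution probability >= ``t``). Non-standard residues split the
    sequence so no window spans them.
    """
    if mode not in ("exact", "substitute_aware"):
        raise ValueError(f"unknown mode {mode!r}")
    if not f.features:
        raise ValueError("empty feature set")
    if mode == "substitute_aware" and (m is None or t is None):
        raise ValueError("substitute_aware mode requires a matrix and threshold T")

    rows = np.zeros((len(s), len(f.features)), dtype=np.uint8)
    for si, (_, seq, _) in enumerate(s.sequences):
        runs = segments(seq)
        for fi, feature in enumerate(f.features):
            if _present_exact(feature, runs):
                rows[si, fi] = 1
            elif mode == "substitute_aware" and _present_substitute(feature, runs, m, t):
                rows[si, fi] = 1
    return BinaryContext(
        feature_names=tuple(f.features),
        ids=tuple(sid for sid, _, _ in s.sequences),
        labels=tuple(s.labels),
        matrix=rows,
    )


def _arff_quote(name: str) -> str:
    if any(ch in name for ch in " ,%{}'\"\t"):
        return "'" + name.replace("'", "\\'") + "'"
    return name


def write_arff(c: BinaryContext, relation_name: str = "sequences") -> str:
    """Render the context in ARFF (WEKA dialect).

    Every feature becomes a nominal {0,1} attribute named by its motif;
    the class is the final nominal attribute. Parsing the output back
    recovers the identical table.
    """
    if len(set(c.feature_names)) != len(c.feature_names):
        raise ValueError("duplicate feature names")
    if c.matrix.shape[0] == 0:
        raise ValueError("context has no rows")
    classes = sorted(set(c.labels))
    out = [f"@relation {_arff_quote(relation_name)}", ""]
    for name in c.feature_names:
        out.append(f"@attribute {_arff_quote(name)} {{0,1}}")
    out.append("@attribute class {" + ",".join(_arff_quote(cl) for cl in classes) + "}")
    out.append("")
    out.append("@data")
    for row, label in zip(c.matrix, c.labels):
        out.append(",".join(str(int(v)) for v in row) + f",{_arff_quote(label)}")
    return "\n".join(out) + "\n"


def write_csv(c: BinaryContext) -> str:
    """Render the context as CSV: feature columns then a final class column."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([*c.feature_names, "class"])
    for row, label in zip(c.matrix, c.labels):
        writer.writerow([*map(int, row), label])
    return buf.getvalue()


def read_csv(text: str, ids: tuple[str, ...] | None = None) -> BinaryContext:
    """Parse a context written by :func:`write_csv` (round-trip inverse)."""
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    features = tuple(header[:-1])
    rows, labels = [], []
    for rec in reader:
        rows.append([int(v) for v in rec[:-1]])
        labels.append(rec[-1])
    if ids is None:
        ids = tuple(str(i) for i in range(len(rows)))
    return BinaryContext(
        feature_names=features,
        ids=ids,
        labels=tuple(labels),
        matrix=np.array(rows, dtype=np.uint8),
    )
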