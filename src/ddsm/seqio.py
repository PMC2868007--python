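"""FASTA input and labeled sequence set assembly.

Two labeling conventions are supported: one FASTA file per family (the
file's label names the family), or a single FASTA plus a two-column TSV
mapping sequence id to family label.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import SeqIO

from .extractors import LabeledSequenceSet

__all__ = ["read_fasta", "load_labeled_set", "EncoderConfig"]


def read_fasta(source) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs, order kept.

    ``source`` is a path or raw FASTA text. Ids are the first
    whitespace-delimited token of the header; sequence line breaks are
    joined.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        handle = open(source)
    elif isinstance(source, str):
        if source.lstrip() and not source.lstrip().startswith(">"):
            raise ValueError("sequence data before first FASTA header")
        handle = io.StringIO(source)
    else:
        handle = source
    with handle:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise ValueError("no FASTA records found")
    return records


def load_labeled_set(
    fasta_by_label: dict[str, object] | None = None,
    fasta: object | None = None,
    labels_tsv: str | None = None,
) -> LabeledSequenceSet:
    """Assemble a :class:`LabeledSequenceSet`.

    Either ``fasta_by_label`` (family label -> FASTA path/text) or
    ``fasta`` + ``labels_tsv`` (id<TAB>label lines) must be given. Every
    sequence must receive exactly one label; duplicate or unlabeled ids
    are errors.
    """
    records: list[tuple[str, str, str]] = []
    if fasta_by_label is not None:
        for label, source in fasta_by_label.items():
            recs = read_fasta(source)
            records.extend((sid, seq, label) for sid, seq in recs)
    elif fasta is not None and labels_tsv is not None:
        label_of: dict[str, str] = {}
        for ln in labels_tsv.splitlines():
            if not ln.strip():
                continue
            sid, _, label = ln.partition("\t")
            if not label:
                raise ValueError(f"malformed label line: {ln!r}")
            label_of[sid.strip()] = label.strip()
        for sid, seq in read_fasta(fasta):
            if sid not in label_of:
                raise ValueError(f"sequence {sid!r} has no label")
            records.append((sid, seq, label_of[sid]))
    else:
        raise ValueError("provide fasta_by_label, or fasta plus labels_tsv")
    return LabeledSequenceSet.from_records(records)


@dataclass
class EncoderConfig:
    """Encoder parameters with the method's published defaults.

    N-grams use N = 3; Active Motifs use min length 3 and 25% activity;
    DD and DDSM use alpha = 0, beta = 0; DDSM uses BLOSUM62 with
    substitution probability threshold T = 0.9.
    """

    method: str = "DDSM"
    n: int = 3
    min_length: int = 3
    max_length: int = 10
    activity_pct: float = 25.0
    mutations: int = 0
    alpha: float = 0.0
    beta: float = 0.0
    matrix_name: str = "BLOSUM62"
    t: float = 0.9
    output_format: str = "arff"
    seed: int = 0
    feature_cap: int = 200_000
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, text: str) -> "EncoderConfig":
        """Build a config from key=value lines ('#' starts a comment)."""
        cfg = cls()
        casts = {f.name: type(getattr(cfg, f.name)) for f in
                 cfg.__dataclass_fields__.values() if f.name != "extra"}
        for ln in text.splitlines():
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            key, sep, value = ln.partition("=")
            key, value = key.strip(), value.strip()
            if not sep:
                raise ValueError(f"malformed config line: {ln!r}")
            if key in casts:
                setattr(cfg, key, casts[key](value))
            else:
                cfg.extra[key] = value
        return cfg
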