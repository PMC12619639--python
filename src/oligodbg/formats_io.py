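"""Sequence I/O, the on-disk subset layout, pipeline configuration and logging.

FASTA/FASTQ parsing goes through Biopython's streaming iterators; records are
validated (alphabet {A,C,G,T,N}, upper-cased, non-empty) on the way in.
Coordinates are 0-based, half-open everywhere in this package.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import sys
from pathlib import Path
from typing import Iterable, Iterator, Optional

import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = frozenset("ACGTN")

#: quality symbol used when writing FASTQ for reads that carry no qualities
DEFAULT_QUALITY_CHAR = "I"

logger = logging.getLogger("oligodbg")


class SequenceFormatError(ValueError):
    """A malformed FASTA/FASTQ record."""


class ConfigError(ValueError):
    """An out-of-range or unknown configuration value."""


def configure_logging(quiet: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("oligodbg")
    root.handlers[:] = [handler]
    root.setLevel(logging.WARNING if quiet else logging.INFO)


@dataclasses.dataclass
class Read:
    """One sequencing read (possibly trimmed/reoriented downstream).

    ``quality``, when present, is a per-base string of the same length as
    ``bases``.
    """

    id: str
    bases: str
    quality: Optional[str] = None


@dataclasses.dataclass
class PipelineParams:
    """Tunable parameters of the partition + consensus pipeline.

    k
        de Bruijn graph k-mer length (nt).
    abundance_threshold
        minimum count for a k-mer to be kept ("solid") when building graphs.
    subset_max_reads
        maximum reads per subset (T); first-level groups above this are
        re-keyed and split.
    key_len_short / key_len_long
        partitioning key lengths: 4 bases give the initial batch of at most
        256 subsets per primer pair, 20 bases the refinement key.
    expected_length
        expected oligonucleotide length N (primers included); usually taken
        from the primer scheme.
    max_primer_mismatch_frac
        fraction of the primer length tolerated as Hamming mismatches when
        anchoring.
    seed_len
        exact-match seed length used to propose anchor offsets.
    max_traversal_steps
        per-subset budget of graph-extension steps.
    """

    k: int = 15
    abundance_threshold: int = 3
    subset_max_reads: int = 2000
    key_len_short: int = 4
    key_len_long: int = 20
    expected_length: Optional[int] = None
    max_primer_mismatch_frac: float = 0.25
    seed_len: int = 8
    max_traversal_steps: int = 1_000_000

    def validate(self) -> "PipelineParams":
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        if self.abundance_threshold < 1:
            raise ConfigError(
                f"abundance_threshold must be >= 1, got {self.abundance_threshold}"
            )
        if self.subset_max_reads < 1:
            raise ConfigError(
                f"subset_max_reads must be >= 1, got {self.subset_max_reads}"
            )
        if self.key_len_short < 1:
            raise ConfigError(f"key_len_short must be >= 1, got {self.key_len_short}")
        if self.key_len_long < self.key_len_short:
            raise ConfigError(
                "key_len_long must be >= key_len_short, got "
                f"{self.key_len_long} < {self.key_len_short}"
            )
        if not (0.0 <= self.max_primer_mismatch_frac <= 1.0):
            raise ConfigError(
                "max_primer_mismatch_frac must be in [0, 1], got "
                f"{self.max_primer_mismatch_frac}"
            )
        if self.seed_len < 1:
            raise ConfigError(f"seed_len must be >= 1, got {self.seed_len}")
        if self.max_traversal_steps < 1:
            raise ConfigError(
                f"max_traversal_steps must be >= 1, got {self.max_traversal_steps}"
            )
        if self.expected_length is not None and self.expected_length < 1:
            raise ConfigError(
                f"expected_length must be positive, got {self.expected_length}"
            )
        return self


_PARAM_FIELDS = {f.name for f in dataclasses.fields(PipelineParams)}


def load_config(path: Optional[str | Path] = None) -> PipelineParams:
    """Load PipelineParams from a YAML or JSON file.

    An absent path (or a path that does not exist) yields all defaults;
    fields missing from the file take their defaults. Unknown keys and
    out-of-range values raise :class:`ConfigError` naming the field.
    """
    if path is None:
        return PipelineParams().validate()
    path = Path(path)
    if not path.exists():
        return PipelineParams().validate()
    with open(path) as fh:
        data = yaml.safe_load(fh)  # YAML superset: also parses JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _PARAM_FIELDS
    if unknown:
        raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
    return PipelineParams(**data).validate()


def _validate_bases(bases: str, where: str) -> str:
    bases = bases.upper()
    if not bases:
        raise SequenceFormatError(f"empty sequence at {where}")
    if not VALID_BASES.issuperset(bases):
        bad = sorted(set(bases) - VALID_BASES)
        raise SequenceFormatError(f"illegal base(s) {bad} at {where}")
    return bases


def detect_format(path: str | Path) -> str:
    """Detect 'fasta' or 'fastq' from the first non-empty character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c = line.lstrip()[0]
                if c == ">":
                    return "fasta"
                if c == "@":
                    return "fastq"
                raise SequenceFormatError(
                    f"cannot detect format of {path}: first record starts with {c!r}"
                )
    return "fasta"  # empty file: arbitrary but valid


def read_sequences(path: str | Path, format: str = "auto") -> Iterator[Read]:
    """Stream Read records from a FASTA or FASTQ file.

    Records are yielded in file order with bases upper-cased; 'N' is
    preserved. An empty file yields nothing. Malformed records raise
    :class:`SequenceFormatError` naming the offending line (FASTQ) or
    record (FASTA).
    """
    fmt = detect_format(path) if format == "auto" else format
    if fmt not in ("fasta", "fastq"):
        raise ConfigError(f"unknown sequence format {fmt!r}")
    with open(path) as fh:
        if fmt == "fasta":
            for i, (title, seq) in enumerate(SimpleFastaParser(fh)):
                yield Read(id=title, bases=_validate_bases(seq, f"record {i + 1} of {path}"))
        else:
            i = 0
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    where = f"line {4 * i + 1} of {path}"
                    if len(qual) != len(seq):
                        raise SequenceFormatError(
                            f"quality length {len(qual)} != sequence length "
                            f"{len(seq)} at {where}"
                        )
                    yield Read(id=title, bases=_validate_bases(seq, where), quality=qual)
                    i += 1
            except ValueError as exc:
                if isinstance(exc, SequenceFormatError):
                    raise
                raise SequenceFormatError(
                    f"malformed FASTQ near line {4 * i + 1} of {path}: {exc}"
                ) from exc


def write_sequences(
    records: Iterable[Read], path: str | Path, format: str = "fasta"
) -> int:
    """Write Read records to ``path``; returns the number written.

    FASTA is wrapped at 80 columns. FASTQ records lacking qualities are
    filled with a constant symbol (logged once).
    """
    if format not in ("fasta", "fastq"):
        raise ConfigError(f"unknown sequence format {format!r}")
    n = 0
    filled = False
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.bases), 80):
                    fh.write(rec.bases[i : i + 80] + "\n")
            else:
                qual = rec.quality
                if qual is None:
                    qual = DEFAULT_QUALITY_CHAR * len(rec.bases)
                    if not filled:
                        logger.info(
                            "filling missing FASTQ qualities with %r",
                            DEFAULT_QUALITY_CHAR,
                        )
                        filled = True
                if len(qual) != len(rec.bases):
                    raise SequenceFormatError(
                        f"quality length mismatch for record {rec.id!r}"
                    )
                fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")
            n += 1
    return n


# --- on-disk subset layout ---------------------------------------------------

_SUBSET_RE = re.compile(r"^subset_p(\d+)_([A-Z]+)_(\d+)\.fasta$")


def subset_filename(primer_index: int, first_level_key: str, chunk_index: int) -> str:
    return f"subset_p{primer_index}_{first_level_key}_{chunk_index:04d}.fasta"


def parse_subset_filename(name: str) -> tuple[int, str, int]:
    m = _SUBSET_RE.match(name)
    if m is None:
        raise SequenceFormatError(f"not a subset file name: {name!r}")
    return int(m.group(1)), m.group(2), int(m.group(3))


def write_subset_files(subsets, out_dir: str | Path) -> list[dict]:
    """Write each subset as FASTA under ``out_dir`` plus a TSV manifest.

    Returns the manifest rows (file, primer_index, key, read count).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sub in subsets:
        name = subset_filename(sub.primer_index, sub.first_level_key, sub.chunk_index)
        write_sequences(sub.reads, out_dir / name, format="fasta")
        manifest.append(
            {
                "file": name,
                "primer_index": sub.primer_index,
                "key": sub.first_level_key,
                "n_reads": len(sub.reads),
            }
        )
    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("file\tprimer_index\tkey\tn_reads\n")
        for row in manifest:
            fh.write(f"{row['file']}\t{row['primer_index']}\t{row['key']}\t{row['n_reads']}\n")
    return manifest
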