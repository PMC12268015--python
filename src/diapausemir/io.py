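"""Readers and writers for catalog, count-matrix and metadata files.

Formats
-------
Hairpins travel as FASTA plus an arm annotation in one of two dialects,
both normalized to the same in-memory :class:`~diapausemir.core.HairpinCatalog`:

* GFF3 — ``miRNA_primary_transcript`` records (ID, family, conserved
  attributes) with child ``miRNA`` records whose coordinates are 1-based
  inclusive positions *on the hairpin sequence* named by the seqid column.
* flat TSV — columns ``locus_id  family  conserved  arm  start  end``,
  one row per arm; a row with ``arm='.'`` declares a locus without
  annotated arms.

Arms are named 5p/3p by their position on the hairpin (earlier start =
5p); a source file whose arm name contradicts its position is rejected,
because the downstream arm-switch analysis depends on positional identity.

Counts are TSV with row key ``locus_id|arm``; metadata is TSV with one
row per sample. All readers reject malformed input with an error naming
the offending record, and every reader/writer pair round-trips exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .core import (
    ARMS,
    HairpinCatalog,
    HairpinEntry,
    Interval,
    MatureArmCountMatrix,
    SampleMeta,
    ValidationError,
    validate_metadata,
)

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _parse_bool(s: str, where: str) -> bool:
    try:
        return _BOOL[s.strip().lower()]
    except KeyError:
        raise ValidationError(f"{where}: cannot parse boolean {s!r}") from None


# ---------------------------------------------------------------------------
# hairpin catalog

def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA record {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValidationError(f"no FASTA records in {path}")
    return seqs


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValidationError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _positional_arms(
    locus_id: str, arms: list[tuple[Interval, str | None]], seq_len: int
) -> tuple[Interval | None, Interval | None]:
    """Order raw arm records positionally and check declared names."""
    if len(arms) > 2:
        raise ValidationError(f"{locus_id}: more than two mature arms annotated")
    arms = sorted(arms, key=lambda t: t[0].start)
    assigned: dict[str, Interval] = {}
    if len(arms) == 1:
        iv, declared = arms[0]
        # single arm: positional call by which half of the hairpin it sits in,
        # unless the source declares a name
        if declared in ARMS:
            assigned[declared] = iv
        else:
            mid = (seq_len + 1) / 2
            center = (iv.start + iv.end) / 2
            assigned["5p" if center <= mid else "3p"] = iv
    elif len(arms) == 2:
        for positional, (iv, declared) in zip(("5p", "3p"), arms):
            if declared is not None and declared != positional:
                raise ValidationError(
                    f"{locus_id}: arm named {declared!r} but positioned as "
                    f"{positional} on the hairpin"
                )
            assigned[positional] = iv
    return assigned.get("5p"), assigned.get("3p")


def _declared_arm(name: str | None) -> str | None:
    if name is None:
        return None
    low = name.lower()
    for arm in ARMS:
        if low.endswith(arm) or f"-{arm}" in low:
            return arm
    return None


def read_catalog(annotation_path: str | Path, hairpin_fasta: str | Path) -> HairpinCatalog:
    """Read a hairpin catalog from FASTA plus GFF3 or TSV arm annotation.

    The dialect is chosen by file content: lines starting with ``##gff`` or
    9 tab-separated columns with numeric columns 4/5 are treated as GFF3.
    """
    seqs = _read_fasta(hairpin_fasta)
    text = Path(annotation_path).read_text()
    first = next(
        (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")), ""
    )
    if text.startswith("##gff") or len(first.split("\t")) == 9:
        return _read_catalog_gff3(text, seqs, annotation_path)
    return _read_catalog_tsv(text, seqs, annotation_path)


def _read_catalog_gff3(
    text: str, seqs: dict[str, str], path: str | Path
) -> HairpinCatalog:
    meta: dict[str, dict] = {}
    arm_records: dict[str, list[tuple[Interval, str | None]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValidationError(f"{path}:{lineno}: expected 9 GFF3 columns")
        seqid, _, ftype, start, end, _, _, _, attrs_s = cols
        attrs = _gff3_attributes(attrs_s)
        if ftype in ("miRNA_primary_transcript", "pre_miRNA"):
            locus = attrs.get("ID", seqid)
            if locus not in seqs:
                raise ValidationError(
                    f"{path}:{lineno}: hairpin {locus!r} missing from FASTA"
                )
            if locus not in meta:
                order.append(locus)
            meta[locus] = {
                "family": attrs.get("family", locus),
                "conserved": _parse_bool(
                    attrs.get("conserved", "false"), f"{path}:{lineno}"
                ),
            }
        elif ftype == "miRNA":
            locus = attrs.get("Parent", seqid)
            if locus not in seqs:
                raise ValidationError(
                    f"{path}:{lineno}: hairpin {locus!r} missing from FASTA"
                )
            iv = Interval(int(start), int(end))
            declared = _declared_arm(attrs.get("Name") or attrs.get("ID"))
            arm_records.setdefault(locus, []).append((iv, declared))
            if locus not in meta:
                order.append(locus)
                meta[locus] = {"family": locus, "conserved": False}
    entries = []
    for locus in order:
        seq = seqs[locus]
        a5, a3 = _positional_arms(locus, arm_records.get(locus, []), len(seq))
        entries.append(
            HairpinEntry(locus, meta[locus]["family"], meta[locus]["conserved"],
                         seq, a5, a3)
        )
    return HairpinCatalog(entries)


def _read_catalog_tsv(
    text: str, seqs: dict[str, str], path: str | Path
) -> HairpinCatalog:
    meta: dict[str, dict] = {}
    arm_records: dict[str, list[tuple[Interval, str | None]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if lineno == 1 and cols[0] == "locus_id":
            continue
        if len(cols) != 6:
            raise ValidationError(f"{path}:{lineno}: expected 6 TSV columns")
        locus, family, conserved_s, arm, start_s, end_s = cols
        if locus not in seqs:
            raise ValidationError(f"{path}:{lineno}: hairpin {locus!r} missing from FASTA")
        if locus not in meta:
            order.append(locus)
            meta[locus] = {
                "family": family,
                "conserved": _parse_bool(conserved_s, f"{path}:{lineno}"),
            }
        if arm == ".":
            continue
        if arm not in ARMS:
            raise ValidationError(f"{path}:{lineno}: arm must be 5p, 3p or '.'")
        iv = Interval(int(start_s), int(end_s))
        arm_records.setdefault(locus, []).append((iv, arm))
    entries = []
    for locus in order:
        seq = seqs[locus]
        a5, a3 = _positional_arms(locus, arm_records.get(locus, []), len(seq))
        entries.append(
            HairpinEntry(locus, meta[locus]["family"], meta[locus]["conserved"],
                         seq, a5, a3)
        )
    return HairpinCatalog(entries)


def write_catalog(
    catalog: HairpinCatalog,
    annotation_path: str | Path,
    hairpin_fasta: str | Path,
    dialect: str = "gff3",
) -> None:
    with open(hairpin_fasta, "w") as fh:
        for e in catalog:
            fh.write(f">{e.locus_id}\n{e.hairpin_seq}\n")
    if dialect == "gff3":
        lines = ["##gff-version 3"]
        for e in catalog:
            n = len(e.hairpin_seq)
            cons = "true" if e.conserved else "false"
            lines.append(
                f"{e.locus_id}\tdiapausemir\tmiRNA_primary_transcript\t1\t{n}\t.\t+\t.\t"
                f"ID={e.locus_id};family={e.family};conserved={cons}"
            )
            for arm in e.arms:
                iv = e.arm_interval(arm)
                lines.append(
                    f"{e.locus_id}\tdiapausemir\tmiRNA\t{iv.start}\t{iv.end}\t.\t+\t.\t"
                    f"ID={e.locus_id}-{arm};Name={e.locus_id}-{arm};Parent={e.locus_id}"
                )
        Path(annotation_path).write_text("\n".join(lines) + "\n")
    elif dialect == "tsv":
        lines = ["locus_id\tfamily\tconserved\tarm\tstart\tend"]
        for e in catalog:
            cons = "true" if e.conserved else "false"
            if not e.arms:
                lines.append(f"{e.locus_id}\t{e.family}\t{cons}\t.\t.\t.")
            for arm in e.arms:
                iv = e.arm_interval(arm)
                lines.append(
                    f"{e.locus_id}\t{e.family}\t{cons}\t{arm}\t{iv.start}\t{iv.end}"
                )
        Path(annotation_path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# count matrix

def read_counts(path: str | Path) -> MatureArmCountMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty counts file") from None
        sample_ids = header[1:]
        arm_ids: list[tuple[str, str]] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, 2):
            if not row:
                continue
            key = row[0]
            if "|" not in key:
                raise ValidationError(f"{path}:{lineno}: row key {key!r} lacks '|'")
            locus, arm = key.rsplit("|", 1)
            if arm not in ARMS:
                raise ValidationError(f"{path}:{lineno}: unknown arm in {key!r}")
            if len(row) - 1 != len(sample_ids):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(sample_ids)} counts, got {len(row) - 1}"
                )
            vals = []
            for col, cell in enumerate(row[1:], 2):
                try:
                    v = int(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: column {col}: non-integer count {cell!r}"
                    ) from None
                if v < 0:
                    raise ValidationError(
                        f"{path}:{lineno}: column {col}: negative count {v}"
                    )
                vals.append(v)
            arm_ids.append((locus, arm))
            rows.append(vals)
    counts = np.array(rows, dtype=np.int64).reshape(len(arm_ids), len(sample_ids))
    return MatureArmCountMatrix(arm_ids, sample_ids, counts)


def write_counts(matrix: MatureArmCountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("arm_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for label, row in zip(matrix.row_labels(), matrix.counts):
            fh.write(label + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# sample metadata

_META_COLS = ("sample_id", "species", "clade", "annual", "status", "replicate")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _META_COLS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"{path}: missing metadata column(s) {missing}")
        samples = []
        for lineno, row in enumerate(reader, 2):
            where = f"{path}:{lineno}"
            try:
                rep = int(row["replicate"])
            except ValueError:
                raise ValidationError(
                    f"{where}: non-integer replicate {row['replicate']!r}"
                ) from None
            samples.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    species=row["species"],
                    clade=row["clade"],
                    annual=_parse_bool(row["annual"], where),
                    status=row["status"],
                    replicate=rep,
                )
            )
    validate_metadata(samples)
    return samples


def write_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_META_COLS) + "\n")
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.species}\t{s.clade}\t"
                f"{'true' if s.annual else 'false'}\t{s.status}\t{s.replicate}\n"
            )
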