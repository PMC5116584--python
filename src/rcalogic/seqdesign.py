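"""Concrete template, splint and primer sequences; operator cross-screening.

A circular template is stored linearized at its ligation junction.  The
splint oligonucleotide is the reverse complement of the head-to-tail
junction (3'-end followed by 5'-end), the primer is the reverse complement
of the primer-binding region, and the circularizable strand carries a
5'-phosphate.

Orthogonality at the sequence level is checked by exact-match scanning of
every operator motif and its reverse complement over the circular sequence,
including matches that wrap around the junction (handled by doubling the
string).  Intended sites are subtracted; any residual occurrence is a
cross-design collision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CircularTemplate
from .defaults import DEFAULT_OPERATOR_SEQUENCES

__all__ = [
    "OperatorRecord",
    "OperatorDB",
    "default_operator_db",
    "TemplateBuild",
    "SpacerPolicy",
    "assemble_template",
    "scan_operators",
    "scan_system",
    "write_fasta",
    "read_fasta",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PRIMER_REGION = "CCTCATCAGTTCGACCTT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OperatorRecord:
    operator_id: str
    sequence: str
    cognate_repressor: str
    note: str = ""

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError(
                f"operator {self.operator_id!r}: sequence must be non-empty "
                "uppercase ACGT"
            )


@dataclass(frozen=True)
class OperatorDB:
    """operator_id -> recognition sequence, with unique sequences."""

    records: Mapping[str, OperatorRecord]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", dict(self.records))
        seqs = [r.sequence for r in self.records.values()]
        if len(seqs) != len(set(seqs)):
            raise ValueError("operator sequences must be unique")

    def __getitem__(self, operator_id: str) -> OperatorRecord:
        return self.records[operator_id]

    def __contains__(self, operator_id: str) -> bool:
        return operator_id in self.records

    def __iter__(self):
        return iter(self.records.values())


def default_operator_db() -> OperatorDB:
    """Literature-motif placeholders; replace with project-specific sequences."""
    return OperatorDB(
        {
            op_id: OperatorRecord(
                operator_id=op_id,
                sequence=seq,
                cognate_repressor=rep,
                note="placeholder motif; replaceable",
            )
            for op_id, (seq, rep) in DEFAULT_OPERATOR_SEQUENCES.items()
        }
    )


@dataclass(frozen=True)
class SpacerPolicy:
    """How operators are separated and the template padded to length.

    Spacers are A/T-balanced; padding is drawn deterministically from
    ``seed`` and regenerated until its GC content lies in ``gc_range`` and
    it introduces no unintended operator occurrence.
    """

    spacer: str = "ATTAAT"
    gc_range: tuple = (0.40, 0.60)
    seed: int = 0


@dataclass(frozen=True)
class TemplateBuild:
    """A buildable oligo set for one circular template.

    ``circular_sequence`` is the circular strand linearized at the ligation
    junction; ``site_coordinates`` are 0-based half-open on that
    linearization.
    """

    name: str
    circular_sequence: str
    splint: str
    primer: str
    site_coordinates: tuple  # of (operator_id, start, end)
    primer_region_span: tuple = (0, 0)
    is_circular: bool = True
    phosphorylated_5prime: bool = True
    note: str = ""
    # Intended sites that span the linearization junction (operator ids);
    # they have no representable half-open coordinates but still count as
    # intended during scanning.  Produced only by :meth:`rotated`.
    wrapped_sites: tuple = ()

    def __post_init__(self) -> None:
        length = len(self.circular_sequence)
        for op_id, start, end in self.site_coordinates:
            if not (0 <= start < end <= length):
                raise ValueError(
                    f"build {self.name!r}: coordinates {start}-{end} for "
                    f"{op_id!r} outside sequence of length {length}"
                )

    def rotated(self, k: int) -> "TemplateBuild":
        """The same circle linearized ``k`` nucleotides downstream.

        A site that comes to span the new junction moves from
        ``site_coordinates`` to ``wrapped_sites``, so scans on rotated
        builds still subtract every intended site.
        """
        length = len(self.circular_sequence)
        k %= length
        seq = self.circular_sequence[k:] + self.circular_sequence[:k]
        coords = []
        wrapped = list(self.wrapped_sites)
        for op_id, start, end in self.site_coordinates:
            new_start = (start - k) % length
            if new_start + (end - start) <= length:
                coords.append((op_id, new_start, new_start + (end - start)))
            else:
                wrapped.append(op_id)
        return TemplateBuild(
            name=self.name,
            circular_sequence=seq,
            splint=self.splint,
            primer=self.primer,
            site_coordinates=tuple(coords),
            primer_region_span=(0, 0),
            is_circular=self.is_circular,
            phosphorylated_5prime=self.phosphorylated_5prime,
            note=self.note,
            wrapped_sites=tuple(wrapped),
        )


def _match_positions(circular_seq: str, motif: str) -> set:
    """Start positions (mod length) where motif or its reverse complement
    matches the circular sequence, junction wrap included."""
    length = len(circular_seq)
    doubled = circular_seq + circular_seq
    rc = reverse_complement(motif)
    positions = set()
    for m in {motif, rc}:
        if len(m) > length:
            continue
        start = 0
        while True:
            hit = doubled.find(m, start)
            if hit == -1 or hit >= length:
                break
            positions.add(hit)
            start = hit + 1
    return positions


def assemble_template(
    template: CircularTemplate,
    operator_db: Optional[OperatorDB] = None,
    spacer_policy: Optional[SpacerPolicy] = None,
    total_length: Optional[int] = None,
    splint_arm: int = 10,
) -> TemplateBuild:
    """Lay out primer region, operators and padding into a circular build.

    The linearized sequence is ``primer_region + (spacer + operator)* +
    padding``; site coordinates are recorded, the splint spans the ligation
    junction and the primer is the reverse complement of the primer-binding
    region.  Raises on unknown operators, a duplicate operator on one
    template, or a target length too short for the content.
    """
    operator_db = operator_db or default_operator_db()
    policy = spacer_policy or SpacerPolicy()
    for site in template.sites:
        if site.operator_id not in operator_db:
            raise KeyError(f"operator {site.operator_id!r} not in database")
    op_ids = [s.operator_id for s in template.sites]
    if len(op_ids) != len(set(op_ids)):
        raise ValueError(
            f"template {template.name!r}: duplicate operator on one template"
        )

    primer_region = template.primer_region or DEFAULT_PRIMER_REGION
    parts = [primer_region]
    coords = []
    pos = len(primer_region)
    for site in template.sites:
        seq = operator_db[site.operator_id].sequence
        parts.append(policy.spacer)
        pos += len(policy.spacer)
        coords.append((site.operator_id, pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    content = "".join(parts)

    target = total_length if total_length is not None else template.total_length
    if target is None:
        target = _round_up(len(content) + 10, 10)
    if target < len(content):
        raise ValueError(
            f"template {template.name!r}: content of {len(content)} nt exceeds "
            f"target length {target}"
        )

    padding = _make_padding(
        target - len(content), content, [c[0] for c in coords], operator_db, policy
    )
    sequence = content + padding
    junction = sequence[-splint_arm:] + sequence[:splint_arm]
    placeholder = any(
        "placeholder" in operator_db[op_id].note for op_id, _, _ in coords
    )
    build = TemplateBuild(
        name=template.name,
        circular_sequence=sequence,
        splint=reverse_complement(junction),
        primer=reverse_complement(primer_region),
        site_coordinates=tuple(coords),
        primer_region_span=(0, len(primer_region)),
        note="placeholder-operators" if placeholder else "",
    )
    residual = scan_operators(build, operator_db)
    offenders = {k: v for k, v in residual.items() if v != 0}
    if offenders:
        raise ValueError(
            f"template {template.name!r}: assembly created unintended operator "
            f"occurrences {offenders}"
        )
    return build


def _round_up(value: int, multiple: int) -> int:
    return ((value + multiple - 1) // multiple) * multiple


def _make_padding(
    length: int,
    content: str,
    intended_ops: Sequence[str],
    db: OperatorDB,
    policy: SpacerPolicy,
) -> str:
    if length == 0:
        return ""
    rng = np.random.default_rng(policy.seed)
    bases = np.array(list("ACGT"))
    lo, hi = policy.gc_range
    for _ in range(200):
        pad = "".join(rng.choice(bases, size=length))
        gc = sum(b in "GC" for b in pad) / length
        if length >= 5 and not lo <= gc <= hi:
            continue
        candidate = content + pad
        clean = True
        for record in db:
            expected = intended_ops.count(record.operator_id)
            if len(_match_positions(candidate, record.sequence)) != expected:
                clean = False
                break
        if clean:
            return pad
    raise RuntimeError("could not generate collision-free padding")  # pragma: no cover


def scan_operators(
    build: TemplateBuild, operator_db: Optional[OperatorDB] = None
) -> dict:
    """Residual operator occurrences after subtracting intended sites.

    Counts distinct start positions where each operator (either orientation)
    matches the circular sequence — wrap-around included — then subtracts
    one per recorded site of that operator.  A nonzero residual marks a
    cross-design collision (or, if negative, a missing intended site).
    """
    operator_db = operator_db or default_operator_db()
    intended: dict = {}
    for op_id in [c[0] for c in build.site_coordinates] + list(build.wrapped_sites):
        intended[op_id] = intended.get(op_id, 0) + 1
    residual = {}
    for record in operator_db:
        found = len(_match_positions(build.circular_sequence, record.sequence))
        residual[record.operator_id] = found - intended.get(record.operator_id, 0)
    return residual


def scan_system(
    builds: Sequence[TemplateBuild], operator_db: Optional[OperatorDB] = None
) -> pd.DataFrame:
    """Template x operator residual-occurrence matrix for a whole design."""
    operator_db = operator_db or default_operator_db()
    rows = {b.name: scan_operators(b, operator_db) for b in builds}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


# ---------------------------------------------------------------------------
# FASTA


def _header_fields(build: TemplateBuild) -> str:
    sites = ",".join(
        f"{op}:{start}-{end}" for op, start, end in build.site_coordinates
    )
    fields = {
        "circular": str(build.is_circular).lower(),
        "phos5": str(build.phosphorylated_5prime).lower(),
        "primer_region": f"{build.primer_region_span[0]}-{build.primer_region_span[1]}",
        "sites": sites,
    }
    if build.note:
        fields["note"] = build.note  # whitespace-free by construction
    return " ".join(f"{k}={v}" for k, v in fields.items())


def write_fasta(builds: Sequence[TemplateBuild], handle=None) -> str:
    """Template, splint and primer records per build, 60-column wrapped.

    Headers carry coordinates as key=value pairs and round-trip through
    :func:`read_fasta`.
    """
    if not builds:
        raise ValueError("no builds to write")
    records = []
    for build in builds:
        records.append(
            SeqRecord(
                Seq(build.circular_sequence),
                id=f"{build.name}|template",
                description=_header_fields(build),
            )
        )
        records.append(
            SeqRecord(
                Seq(build.splint), id=f"{build.name}|splint", description=""
            )
        )
        records.append(
            SeqRecord(
                Seq(build.primer), id=f"{build.name}|primer", description=""
            )
        )
    buffer = io.StringIO()
    SeqIO.write(records, buffer, "fasta")
    text = buffer.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def read_fasta(text: str) -> list:
    """Rebuild :class:`TemplateBuild` objects from :func:`write_fasta` output."""
    parts: dict = {}
    order: list = []
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        name, _, kind = record.id.partition("|")
        if name not in parts:
            parts[name] = {}
            order.append(name)
        parts[name][kind] = record
    builds = []
    for name in order:
        entry = parts[name]
        template = entry["template"]
        fields = dict(
            kv.split("=", 1)
            for kv in template.description.split()
            if "=" in kv
        )
        coords = []
        if fields.get("sites"):
            for chunk in fields["sites"].split(","):
                op, _, span = chunk.partition(":")
                start, _, end = span.partition("-")
                coords.append((op, int(start), int(end)))
        pr_start, _, pr_end = fields.get("primer_region", "0-0").partition("-")
        builds.append(
            TemplateBuild(
                name=name,
                circular_sequence=str(template.seq),
                splint=str(entry["splint"].seq),
                primer=str(entry["primer"].seq),
                site_coordinates=tuple(coords),
                primer_region_span=(int(pr_start), int(pr_end)),
                is_circular=fields.get("circular", "true") == "true",
                phosphorylated_5prime=fields.get("phos5", "true") == "true",
                note=fields.get("note", ""),
            )
        )
    return builds
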