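"""Reading MANTA-style SV VCFs, quality filtering, and the cohort manifest.

SVRecord coordinates are 0-based half-open internally (VCF POS/END are
1-based at the boundary).  An insertion occupies the single anchor base
[POS, POS+1).  Breakends (BND) are one record per breakend; mates are
paired via MATEID when present, otherwise via the bracket-notation ALT
coordinates.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "SVRecord",
    "CohortManifest",
    "ManifestError",
    "read_sv_vcf",
    "filter_calls",
    "read_manifest",
    "write_sv_vcf",
    "SV_TYPES",
]

SV_TYPES = ("DEL", "INS", "DUP", "INV", "BND")

_BND_ALT = re.compile(r"[\[\]](?P<chrom>[^:\[\]]+):(?P<pos>\d+)[\[\]]")


def _info_get(info, key):
    """INFO access tolerant of keys missing from the VCF header."""
    try:
        return info.get(key)
    except (KeyError, ValueError):
        return None


@dataclass(frozen=True)
class SVRecord:
    """One structural variant call for one sample."""

    sample_id: str
    sv_type: str
    chrom: str
    start: int          # 0-based
    end: int            # 0-based exclusive; for BND the breakend base + 1
    length: int         # |SVLEN| when given, else end - start; bp
    filter_status: str = "PASS"
    id: str = "."
    mate: tuple[str, int] | None = None   # BND only: (chrom, 0-based pos)
    event_key: str = ""                   # shared by BND mates / caller event

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.start >= self.end:
            raise ValueError(
                f"{self.id}: start {self.start} >= end {self.end}")
        if self.length < 0:
            raise ValueError(f"{self.id}: negative length")
        if not self.event_key:
            object.__setattr__(self, "event_key", self.id)

    @property
    def unpaired(self) -> bool:
        return self.sv_type == "BND" and self.mate is None


@dataclass
class CohortManifest:
    """sample -> (phenotype, stratum) map for a case-control cohort."""

    samples: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, sample_id: str, phenotype: str, stratum: str) -> None:
        if sample_id in self.samples:
            raise ManifestError(f"duplicate sample_id {sample_id!r}")
        if phenotype not in ("case", "control"):
            raise ManifestError(
                f"sample {sample_id!r}: phenotype must be case/control, "
                f"got {phenotype!r}")
        self.samples[sample_id] = (phenotype, stratum)

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.samples

    @property
    def strata(self) -> list[str]:
        return sorted({s for _, s in self.samples.values()})

    def stratum_samples(self, stratum: str, phenotype: str | None = None) -> list[str]:
        return sorted(
            sid for sid, (ph, st) in self.samples.items()
            if st == stratum and (phenotype is None or ph == phenotype))

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for ph, st in self.samples.values():
            out.setdefault(st, {"case": 0, "control": 0})[ph] += 1
        return out

    def validate(self) -> None:
        for st, c in self.counts().items():
            if c["case"] == 0 or c["control"] == 0:
                raise ManifestError(
                    f"stratum {st!r} lacks cases or controls: {c}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tphenotype\tstratum\n")
            for sid in sorted(self.samples):
                ph, st = self.samples[sid]
                fh.write(f"{sid}\t{ph}\t{st}\n")


class ManifestError(ValueError):
    pass


def read_manifest(source: str | Path | TextIO) -> CohortManifest:
    """Read a sample manifest TSV (columns sample_id, phenotype, stratum)."""
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source)
        close = True
    else:
        fh = source
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "phenotype", "stratum"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ManifestError(
                f"manifest header must contain {sorted(required)}, "
                f"got {reader.fieldnames}")
        manifest = CohortManifest()
        for row in reader:
            manifest.add(row["sample_id"], row["phenotype"], row["stratum"])
    finally:
        if close:
            fh.close()
    logger.info("manifest: %s", manifest.counts())
    return manifest


def _parse_bnd_alt(alt: str) -> tuple[str, int] | None:
    m = _BND_ALT.search(alt)
    if m is None:
        return None
    return m.group("chrom"), int(m.group("pos")) - 1


def _records_from_variant(rec, sample_id: str, sample_name: str | None) -> list[SVRecord]:
    info = rec.info
    svtype = _info_get(info, "SVTYPE")
    alts = rec.alts or ()
    out: list[SVRecord] = []
    for alt in alts:
        sv_type = svtype
        if sv_type is None:
            if alt and alt.startswith("<") and alt.endswith(">"):
                sv_type = alt[1:-1].split(":")[0]
            elif alt and ("[" in alt or "]" in alt):
                sv_type = "BND"
            else:
                logger.warning("record %s: SVTYPE missing and ALT %r not "
                               "symbolic; skipped", rec.id, alt)
                continue
        if sv_type == "TRA":
            sv_type = "BND"
        sv_type = sv_type.split(":")[0]   # DUP:TANDEM -> DUP
        if sv_type not in SV_TYPES:
            logger.warning("record %s: unsupported SVTYPE %r skipped",
                           rec.id, sv_type)
            continue
        start = rec.start                  # pysam: 0-based
        svlen = _info_get(info, "SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        if sv_type == "BND":
            end = start + 1
            mate = _parse_bnd_alt(alt)
            if mate is None:
                logger.warning("record %s: BND ALT %r without mate "
                               "coordinates; kept unpaired", rec.id, alt)
            length = 0
            event_key = (_info_get(info, "EVENT") or _bnd_event_key(rec.id, info)
                         or rec.id or ".")
        else:
            mate = None
            if sv_type == "INS":
                end = start + 1
            elif svlen is not None:
                # for DEL/DUP/INV the span equals |SVLEN|; htslib's stop is
                # unreliable when both END and SVLEN are present
                end = start + abs(int(svlen))
            else:
                end = rec.stop          # derived from INFO END
            length = abs(int(svlen)) if svlen is not None else end - start
            event_key = _info_get(info, "EVENT") or rec.id or "."
        filt = ";".join(rec.filter.keys()) or "."   # "." = unfiltered
        out.append(SVRecord(
            sample_id=sample_id, sv_type=sv_type, chrom=rec.chrom,
            start=start, end=end, length=length, filter_status=filt,
            id=rec.id or ".", mate=mate, event_key=str(event_key)))
    return out


def _bnd_event_key(rec_id: str | None, info) -> str | None:
    """Shared key for a breakend pair: MANTA ids end in :0 / :1."""
    mateid = _info_get(info, "MATEID")
    if isinstance(mateid, (tuple, list)):
        mateid = mateid[0] if mateid else None
    if rec_id and mateid:
        return ":".join(sorted([rec_id, str(mateid)]))
    return None


def read_sv_vcf(path: str | Path, sample_id: str | None = None) -> list[SVRecord]:
    """Read SV records from a VCF 4.x file.

    For a single-sample VCF (or a site-only VCF) all records are attributed
    to ``sample_id`` (defaults to the VCF's sample name, or the file stem).
    For a multi-sample VCF a record is attributed to every sample with a
    non-reference genotype.
    """
    out: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        for rec in vf:
            if len(vcf_samples) > 1 and sample_id is None:
                carriers = [
                    s for s in vcf_samples
                    if any(a not in (None, 0) for a in (rec.samples[s].get("GT") or ()))
                ]
            else:
                carriers = [sample_id or (vcf_samples[0] if vcf_samples
                                          else Path(path).stem)]
            for sid in carriers:
                out.extend(_records_from_variant(rec, sid, None))
    return out


def filter_calls(records: Sequence[SVRecord], min_len: int = 50,
                 require_pass: bool = True) -> list[SVRecord]:
    """Apply quality filters: PASS status and a minimum length.

    Breakends carry no meaningful SVLEN and are exempt from the length
    rule; they are kept or dropped on filter status alone.
    """
    out = []
    for r in records:
        if require_pass and r.filter_status != "PASS":
            continue
        if r.sv_type != "BND" and r.length < min_len:
            continue
        out.append(r)
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.1
##source=svburden-simulator
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Difference in length between REF and ALT alleles">
##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">
##ALT=<ID=INV,Description="Inversion">
##FILTER=<ID=MinQUAL,Description="QUAL below threshold">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_sv_vcf(records: Sequence[SVRecord], path: str | Path,
                 sample_id: str | None = None,
                 contigs: Iterable[tuple[str, int]] | None = None) -> None:
    """Write records as a MANTA-dialect single-sample VCF (plain text)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.id))
    if sample_id is None:
        sample_id = recs[0].sample_id if recs else "sample"
    lines = [_VCF_HEADER]
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={name},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
    mates: dict[tuple[str, int], list[SVRecord]] = {}
    for r in recs:
        if r.sv_type == "BND":
            mates.setdefault((r.chrom, r.start), []).append(r)
    for r in recs:
        pos1 = r.start + 1
        if r.sv_type == "BND":
            if r.mate is None:
                alt = "N."
                info = "SVTYPE=BND"
            else:
                mchrom, mpos = r.mate
                alt = f"N[{mchrom}:{mpos + 1}["
                info = "SVTYPE=BND"
                partner = [m for m in mates.get((mchrom, mpos), [])
                           if m.id != r.id]
                if partner:
                    info += f";MATEID={partner[0].id}"
        elif r.sv_type == "INS":
            alt = "<INS>"
            info = f"SVTYPE=INS;SVLEN={r.length}"
        else:
            alt = f"<{r.sv_type}>"
            svlen = -r.length if r.sv_type == "DEL" else r.length
            info = f"SVTYPE={r.sv_type};END={r.end};SVLEN={svlen}"
        lines.append(f"{r.chrom}\t{pos1}\t{r.id}\tN\t{alt}\t.\t"
                     f"{r.filter_status}\t{info}\tGT\t0/1\n")
    Path(path).write_text("".join(lines))


def pair_breakends(records: Sequence[SVRecord]) -> list[SVRecord]:
    """Fill in BND mate links within one sample's record list.

    Records whose ALT lacked coordinates are paired through MATEID-derived
    shared event keys when possible; the rest stay flagged unpaired.
    """
    by_key: dict[str, list[int]] = {}
    out = list(records)
    for i, r in enumerate(out):
        if r.sv_type == "BND":
            by_key.setdefault(r.event_key, []).append(i)
    for key, idxs in by_key.items():
        if len(idxs) != 2:
            continue
        i, j = idxs
        if out[i].mate is None:
            out[i] = replace(out[i], mate=(out[j].chrom, out[j].start))
        if out[j].mate is None:
            out[j] = replace(out[j], mate=(out[i].chrom, out[i].start))
    return out
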