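"""Shared genotype data model and readers/writers for the standard formats.

The pipeline moves genotypes between VCF, Genepop, NewHybrids and plain
delimited tables.  All of them are mapped onto a single in-memory container,
:class:`GenotypeMatrix`: a samples x loci array of unordered diploid allele
pairs with an explicit MISSING sentinel and optional population labels.

Allele coding
-------------
Alleles are small positive integers (1-based, Genepop style); ``0`` is the
MISSING sentinel and never a valid allele.  A call is missing iff both allele
slots are 0.  Calls are stored sorted, so ``(2, 1)`` and ``(1, 2)`` are the
same heterozygote.  Coordinates are 1-based inclusive throughout (VCF
convention); strands are not tracked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = 0

_IUPAC = set("ACGTRYSWKMBDHVN")


class PanelFormatError(ValueError):
    """A file failed to parse under the named standard."""


class PanelValidationError(ValueError):
    """A record violates an invariant of its type."""


# ---------------------------------------------------------------------------
# container


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid genotype calls with optional population labels.

    Parameters
    ----------
    sample_ids, locus_ids
        Row and column identifiers (opaque strings).
    calls
        ``(n_samples, n_loci, 2)`` integer array of allele codes; ``0`` marks
        a missing allele and a ``(0, 0)`` pair a missing call.  Pairs are
        normalised to sorted order on construction.
    populations
        Optional ``sample_id -> population label`` map.  Species identity is
        carried only through these labels.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    populations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids), 2):
            raise PanelValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if (self.calls < 0).any():
            raise PanelValidationError("negative allele codes are not allowed")
        # half-missing calls are not representable in any supported format
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise PanelValidationError("half-missing calls (one allele 0) found")
        self.calls = np.sort(self.calls, axis=2)
        if self.populations is not None:
            unknown = set(self.populations) - set(self.sample_ids)
            if unknown:
                raise PanelValidationError(f"population labels for unknown samples: {sorted(unknown)}")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_samples, n_loci)`` mask of missing calls."""
        return (self.calls == MISSING).all(axis=2)

    def pop_of(self, sample_id: str) -> str | None:
        return None if self.populations is None else self.populations.get(sample_id)

    def pop_labels(self) -> list[str]:
        if self.populations is None:
            return []
        seen: list[str] = []
        for s in self.sample_ids:
            p = self.populations.get(s)
            if p is not None and p not in seen:
                seen.append(p)
        return seen

    def samples_in_pop(self, pop: str) -> np.ndarray:
        """Row indices of samples carrying population label ``pop``."""
        if self.populations is None:
            raise PanelValidationError("matrix carries no population labels")
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.populations.get(s) == pop],
            dtype=int,
        )

    # -- views -------------------------------------------------------------

    def locus_alleles(self, j: int) -> list[int]:
        """Sorted distinct allele codes observed at locus column ``j``."""
        a = self.calls[:, j, :]
        return sorted(int(x) for x in np.unique(a) if x != MISSING)

    def dosage(self, alt_allele: np.ndarray | None = None) -> np.ndarray:
        """Biallelic dosage matrix: count of the alternate allele, -1 missing.

        The alternate allele defaults to the largest observed code per locus;
        pass ``alt_allele`` (length ``n_loci``) to pin the orientation.
        """
        if alt_allele is None:
            alt_allele = np.array(
                [max(self.locus_alleles(j), default=2) for j in range(self.n_loci)]
            )
        alt = np.asarray(alt_allele)[None, :, None]
        dos = (self.calls == alt).sum(axis=2).astype(np.int8)
        dos[self.missing_mask()] = -1
        return dos

    def subset(self, samples: Sequence[int] | None = None, loci: Sequence[int] | None = None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        li = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        sids = [self.sample_ids[i] for i in si]
        pops = None
        if self.populations is not None:
            pops = {s: self.populations[s] for s in sids if s in self.populations}
        return GenotypeMatrix(
            sample_ids=sids,
            locus_ids=[self.locus_ids[j] for j in li],
            calls=self.calls[np.ix_(si, li)].copy(),
            populations=pops,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
            and (self.populations or {}) == (other.populations or {})
        )


def from_dosage(
    dosage: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    locus_ids: Sequence[str] | None = None,
    populations: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Build a biallelic matrix (alleles 1/2) from a dosage array (-1 = missing)."""
    dosage = np.asarray(dosage)
    n, m = dosage.shape
    sample_ids = list(sample_ids) if sample_ids is not None else [f"S{i:04d}" for i in range(n)]
    locus_ids = list(locus_ids) if locus_ids is not None else [f"L{j:04d}" for j in range(m)]
    calls = np.zeros((n, m, 2), dtype=np.int32)
    calls[dosage == 0] = (1, 1)
    calls[dosage == 1] = (1, 2)
    calls[dosage == 2] = (2, 2)
    return GenotypeMatrix(sample_ids, locus_ids, calls, dict(populations) if populations else None)


# ---------------------------------------------------------------------------
# locus / probe metadata


@dataclass
class LocusRecord:
    """Metadata for a candidate panel locus.

    ``theta`` (Weir–Cockerham FST between the two species samples) and ``pi``
    (nucleotide diversity within the focal species) are filled in by the
    selection stage.  ``cm_position`` must accompany ``linkage_group``.
    """

    locus_id: str
    contig: str
    position: int
    alleles: list[str] = field(default_factory=lambda: ["A", "C"])
    flank_left: str = ""
    flank_right: str = ""
    linkage_group: str | None = None
    cm_position: float | None = None
    theta: float | None = None
    pi: float | None = None

    def __post_init__(self) -> None:
        for flank in (self.flank_left, self.flank_right):
            bad = set(flank.upper()) - _IUPAC
            if bad:
                raise PanelValidationError(
                    f"{self.locus_id}: non-IUPAC symbols in flank: {sorted(bad)}"
                )
        if (self.linkage_group is None) != (self.cm_position is None):
            raise PanelValidationError(
                f"{self.locus_id}: linkage_group and cm_position must be present together"
            )
        if self.cm_position is not None and self.cm_position < 0:
            raise PanelValidationError(f"{self.locus_id}: negative cM position")


MIN_AMPLICON_LEN = 80
MAX_AMPLICON_LEN = 150


@dataclass
class ProbeRecord:
    """Locus-specific primer pair plus the two allele probes.

    Accepted records must target an amplicon between 80 and 150 bp and carry
    probes differing at >= 1 position.
    """

    locus_id: str
    fwd_primer: str
    rev_primer: str
    probe_allele1: str
    probe_allele2: str
    expected_amplicon_length: int

    def __post_init__(self) -> None:
        if self.probe_allele1 == self.probe_allele2:
            raise PanelValidationError(f"{self.locus_id}: identical allele probes")
        if not (MIN_AMPLICON_LEN <= self.expected_amplicon_length <= MAX_AMPLICON_LEN):
            raise PanelValidationError(
                f"{self.locus_id}: amplicon length {self.expected_amplicon_length} "
                f"outside [{MIN_AMPLICON_LEN}, {MAX_AMPLICON_LEN}]"
            )


# ---------------------------------------------------------------------------
# Genepop


def _genepop_code(pair: np.ndarray, digits: int) -> str:
    if pair[0] == MISSING:
        return "0" * (2 * digits)
    return f"{pair[0]:0{digits}d}{pair[1]:0{digits}d}"


def write_genepop(gm: GenotypeMatrix, path: str | Path, title: str = "gtpanel export", digits: int = 2) -> None:
    """Write a Genepop file; samples grouped into POP blocks by label."""
    if gm.calls.max(initial=0) >= 10**digits:
        raise PanelFormatError(f"allele codes exceed {digits}-digit Genepop width")
    path = Path(path)
    pops = gm.pop_labels() or ["pop1"]
    lines = [title]
    lines.extend(gm.locus_ids)
    for pop in pops:
        lines.append("POP")
        if gm.populations is None:
            rows = range(gm.n_samples)
        else:
            rows = gm.samples_in_pop(pop)
        for i in rows:
            codes = " ".join(_genepop_code(gm.calls[i, j], digits) for j in range(gm.n_loci))
            lines.append(f"{gm.sample_ids[i]} ,  {codes}")
    path.write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read Genepop with auto-detected 2- or 3-digit allele codes.

    Population labels are ``pop1``, ``pop2``, ... in POP-block order; all-zero
    codes map to MISSING.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    if len(raw) < 3:
        raise PanelFormatError(f"{path}: truncated Genepop file")
    body = raw[1:]
    # locus names: one per line (or a single comma-separated line) until first POP
    locus_ids: list[str] = []
    idx = 0
    while idx < len(body) and body[idx].strip().upper() != "POP":
        chunk = body[idx].strip()
        if chunk:
            locus_ids.extend(x.strip() for x in chunk.split(",") if x.strip())
        idx += 1
    if idx == len(body):
        raise PanelFormatError(f"{path}: no POP block found")
    sample_ids: list[str] = []
    populations: dict[str, str] = {}
    rows: list[list[str]] = []
    pop_no = 0
    for lineno, line in enumerate(body[idx:], start=idx + 2):
        s = line.strip()
        if not s:
            continue
        if s.upper() == "POP":
            pop_no += 1
            continue
        if "," not in s:
            raise PanelFormatError(f"{path}:{lineno}: expected 'sample , codes'")
        name, codes = s.split(",", 1)
        toks = codes.split()
        if len(toks) != len(locus_ids):
            raise PanelFormatError(
                f"{path}:{lineno}: {len(toks)} genotypes for {len(locus_ids)} loci"
            )
        sample_ids.append(name.strip())
        populations[name.strip()] = f"pop{pop_no}"
        rows.append(toks)
    widths = {len(t) for r in rows for t in r}
    if not widths <= {4, 6}:
        raise PanelFormatError(f"{path}: mixed or unsupported genotype code widths {sorted(widths)}")
    digits = 3 if widths == {6} else 2
    calls = np.zeros((len(rows), len(locus_ids), 2), dtype=np.int32)
    for i, r in enumerate(rows):
        for j, tok in enumerate(r):
            a, b = int(tok[:digits]), int(tok[digits:])
            if a == 0 or b == 0:
                a = b = MISSING
            calls[i, j] = (a, b)
    return GenotypeMatrix(sample_ids, locus_ids, calls, populations)


# ---------------------------------------------------------------------------
# delimited genotype table


def write_table(gm: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a delimited table: sample_id, population, then one a/b column per locus."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join(["sample_id", "population"] + list(gm.locus_ids)) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            pop = gm.pop_of(sid) or ""
            cells = []
            for j in range(gm.n_loci):
                a, b = gm.calls[i, j]
                cells.append("./." if a == MISSING else f"{a}/{b}")
            fh.write(sep.join([sid, pop] + cells) + "\n")


def read_table(path: str | Path, sep: str = "\t") -> GenotypeMatrix:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise PanelFormatError(f"{path}: empty table")
    header = lines[0].split(sep)
    if header[:2] != ["sample_id", "population"]:
        raise PanelFormatError(f"{path}:1: header must start with sample_id{sep}population")
    locus_ids = header[2:]
    sample_ids, populations, rows = [], {}, []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        if len(cells) != len(header):
            raise PanelFormatError(f"{path}:{lineno}: ragged row ({len(cells)} of {len(header)} fields)")
        sample_ids.append(cells[0])
        if cells[1]:
            populations[cells[0]] = cells[1]
        rows.append(cells[2:])
    calls = np.zeros((len(rows), len(locus_ids), 2), dtype=np.int32)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r):
            if cell in ("./.", "", "."):
                continue
            m = re.fullmatch(r"(\d+)/(\d+)", cell)
            if not m:
                raise PanelFormatError(f"{path}:{i + 2}: bad genotype cell {cell!r}")
            a, b = int(m.group(1)), int(m.group(2))
            if a == 0 or b == 0:
                a = b = MISSING
            calls[i, j] = (a, b)
    return GenotypeMatrix(sample_ids, locus_ids, calls, populations or None)


# ---------------------------------------------------------------------------
# VCF (GT field only)


def read_vcf(path: str | Path, pop_map: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF; REF maps to allele 1, ALT alleles to 2, 3, ...

    Only site identity and the GT field are used.  ``./.`` maps to MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        locus_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.array(var.genotypes)[:, :2]  # drop phase flag
        col = gt + 1  # 0-based allele index -> 1-based code
        col[gt < 0] = MISSING
        col[(col == MISSING).any(axis=1)] = MISSING
        cols.append(col)
    vcf.close()
    calls = (
        np.stack(cols, axis=1).astype(np.int32)
        if cols
        else np.zeros((len(sample_ids), 0, 2), dtype=np.int32)
    )
    pops = dict(pop_map) if pop_map else None
    return GenotypeMatrix(sample_ids, locus_ids, calls, pops)


def read_pop_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Two-column sidecar file: sample_id <sep> population."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(sep)
        if len(parts) < 2:
            raise PanelFormatError(f"{path}:{lineno}: expected two columns")
        out[parts[0].strip()] = parts[1].strip()
    return out


def read_genotypes(path: str | Path, format: str, pop_map: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Dispatch reader: ``format`` in {vcf, genepop, table}."""
    if format == "vcf":
        return read_vcf(path, pop_map)
    if format == "genepop":
        gm = read_genepop(path)
    elif format == "table":
        gm = read_table(path)
    else:
        raise PanelValidationError(f"unknown genotype format {format!r}")
    if pop_map:
        gm.populations = dict(pop_map)
    return gm


# ---------------------------------------------------------------------------
# NewHybrids individual-data format


def write_newhybrids(
    gm: GenotypeMatrix,
    z_map: Mapping[str, int] | None,
    path: str | Path,
) -> None:
    """Write the NewHybrids individual-data format with optional z designations.

    ``z_map`` maps sample ids to a known-class index (0 = first pure class,
    1 = second); samples absent from the map carry no z flag.  Genotypes are
    lumped 2-digit codes, ``00`` components for missing.
    """
    z_map = dict(z_map or {})
    unknown = set(z_map) - set(gm.sample_ids)
    if unknown:
        raise PanelValidationError(f"z designations for unknown samples: {sorted(unknown)}")
    if gm.calls.max(initial=0) > 9:
        raise PanelFormatError("allele codes above 9 need a wider digit encoding than NewHybrids lumped format")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"NumIndivs {gm.n_samples}\n")
        fh.write(f"NumLoci {gm.n_loci}\n")
        fh.write("Digits 1\nFormat Lumped\n")
        fh.write("LocusNames " + " ".join(gm.locus_ids) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            parts = [str(i + 1)]
            if sid in z_map:
                parts.append(f"z{z_map[sid]}")
            for j in range(gm.n_loci):
                a, b = gm.calls[i, j]
                parts.append("0" if a == MISSING else f"{a}{b}")
            fh.write(" ".join(parts) + "\n")


def read_newhybrids(path: str | Path) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Re-parse a file written by :func:`write_newhybrids` (own dialect only)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    head = {}
    li = 0
    for li, ln in enumerate(lines):
        key = ln.split()[0]
        if key == "LocusNames":
            locus_ids = ln.split()[1:]
            break
        head[key] = ln.split(maxsplit=1)[1] if " " in ln else ""
    else:
        raise PanelFormatError(f"{path}: missing LocusNames header")
    n = int(head["NumIndivs"])
    m = int(head["NumLoci"])
    if len(locus_ids) != m:
        raise PanelFormatError(f"{path}: LocusNames count != NumLoci")
    calls = np.zeros((n, m, 2), dtype=np.int32)
    sample_ids, z_map = [], {}
    for row, ln in enumerate(lines[li + 1 :]):
        toks = ln.split()
        sid = toks[0]
        sample_ids.append(sid)
        geno = toks[1:]
        if geno and geno[0].startswith("z"):
            z_map[sid] = int(geno[0][1:])
            geno = geno[1:]
        if len(geno) != m:
            raise PanelFormatError(f"{path}: row {row + 1} has {len(geno)} of {m} genotypes")
        for j, tok in enumerate(geno):
            if tok == "0":
                continue
            calls[row, j] = (int(tok[0]), int(tok[1]))
    if len(sample_ids) != n:
        raise PanelFormatError(f"{path}: {len(sample_ids)} rows for NumIndivs {n}")
    return GenotypeMatrix(sample_ids, locus_ids, calls), z_map


# ---------------------------------------------------------------------------
# probe table


_PROBE_FIELDS = [
    "locus_id",
    "fwd_primer",
    "rev_primer",
    "probe_allele1",
    "probe_allele2",
    "expected_amplicon_length",
]


def write_probe_table(probes: Iterable[ProbeRecord], path: str | Path, sep: str = "\t") -> None:
    with Path(path).open("w") as fh:
        fh.write(sep.join(_PROBE_FIELDS) + "\n")
        for p in probes:
            fh.write(
                sep.join(
                    [p.locus_id, p.fwd_primer, p.rev_primer, p.probe_allele1, p.probe_allele2, str(p.expected_amplicon_length)]
                )
                + "\n"
            )


def read_probe_table(path: str | Path, sep: str = "\t") -> list[ProbeRecord]:
    """Read a delimited probe table, validating every record.

    Raises on duplicate locus ids, identical allele probes, or amplicon
    lengths outside the accepted 80–150 bp window.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise PanelFormatError(f"{path}: empty probe table")
    header = lines[0].split(sep)
    missing = [f for f in _PROBE_FIELDS if f not in header]
    if missing:
        raise PanelFormatError(f"{path}: header lacks fields {missing}")
    col = {f: header.index(f) for f in _PROBE_FIELDS}
    out: list[ProbeRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        lid = cells[col["locus_id"]]
        if lid in seen:
            raise PanelValidationError(f"{path}:{lineno}: duplicate locus_id {lid!r}")
        seen.add(lid)
        try:
            out.append(
                ProbeRecord(
                    locus_id=lid,
                    fwd_primer=cells[col["fwd_primer"]],
                    rev_primer=cells[col["rev_primer"]],
                    probe_allele1=cells[col["probe_allele1"]],
                    probe_allele2=cells[col["probe_allele2"]],
                    expected_amplicon_length=int(cells[col["expected_amplicon_length"]]),
                )
            )
        except PanelValidationError as exc:
            raise PanelValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# plain-text config


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a ``key: value`` plain-text config; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.split("#", 1)[0].strip()
        if not s:
            continue
        if ":" not in s:
            raise PanelFormatError(f"{path}:{lineno}: expected 'key: value'")
        k, v = s.split(":", 1)
        out[k.strip()] = v.strip()
    return out
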