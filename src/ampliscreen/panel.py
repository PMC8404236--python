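"""Variant panel model and published cohort frequency tables.

This module is the single source of truth for the screened panel: variant
coordinates (hg38, 1-based as printed in the source tables), alleles,
phenotype labels, and the 1-5 variant-origin categories. It also ships the
two published carrier-frequency tables as verbatim TSV fixtures and builds
synthetic per-variant amplicon reference sequences used by the simulator and
the genotyper.

Conventions
-----------
* Manifest positions are 1-based (VCF-style anchored ref/alt strings, kept
  exactly as printed; indels are not re-normalized).
* Amplicon-local offsets are 0-based half-open.
* Phenotype identity is exact string equality of the table's phenotype
  column, so "distinct conditions" counts reproduce the published totals
  without curation judgments.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field, replace
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantDef",
    "AmpliconTarget",
    "CohortTableRow",
    "POPULATIONS",
    "load_panel_manifest",
    "write_panel_manifest",
    "load_cohort_table",
    "default_panel",
    "load_table1",
    "load_table3",
    "build_amplicons",
    "alt_haplotype",
    "fixture_path",
    "fixture_sha256",
]

POPULATIONS = ("syrian_full", "syrian_mixed", "iranian_mixed", "ashkenazi")

#: TSV column layout of the two shipped cohort tables: population -> (count, %).
TABLE1_COLUMNS: Mapping[str, tuple[str, str]] = {
    "syrian_full": ("syrian_full", "syrian_full_pct"),
    "ashkenazi": ("ashkenazi", "ashkenazi_pct"),
}
TABLE3_COLUMNS: Mapping[str, tuple[str, str]] = {
    "syrian_mixed": ("syrian_mixed", "syrian_mixed_pct"),
    "iranian_mixed": ("iranian_mixed", "iranian_mixed_pct"),
    "ashkenazi": ("ashkenazi", "ashkenazi_pct"),
}

_DNA_RE = re.compile(r"^[ACGT]+$")
_MANIFEST_COLUMNS = [
    "variant_id", "chrom", "pos_hg38", "end_hg38", "rsid", "ref", "alt",
    "gene", "omim", "hgvs_c", "hgvs_p", "phenotype", "category",
]

# Fixed internal seed for the synthetic amplicon reference sequences. The
# amplicons play the role of a reference genome: they must be identical
# across runs regardless of the user's simulation seed.
_REFERENCE_SEED = 791_621


@dataclass(frozen=True)
class VariantDef:
    """One screened panel variant.

    ``ref``/``alt`` are anchored allele strings exactly as printed; a region
    deletion (CNV) carries ``end_hg38`` and empty alleles, and a short
    tandem-repeat expansion is marked by an ``alt`` ending in ``>>``. Only
    plain SNV/indel records are genotyped from reads.
    """

    variant_id: str
    chrom: str
    pos_hg38: int
    ref: str
    alt: str
    gene: str
    omim: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    phenotype: str = ""
    category: int | None = None
    rsid: str = ""
    end_hg38: int | None = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if self.pos_hg38 <= 0:
            raise ValueError(f"{self.variant_id}: pos_hg38 must be positive")
        if self.category is not None and self.category not in {1, 2, 3, 4, 5}:
            raise ValueError(f"{self.variant_id}: category must be in 1..5")
        if self.is_sequence_variant and self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref and alt are identical")
        if self.end_hg38 is not None and self.end_hg38 < self.pos_hg38:
            raise ValueError(f"{self.variant_id}: end before start")

    @property
    def is_region_deletion(self) -> bool:
        return self.end_hg38 is not None

    @property
    def is_repeat_expansion(self) -> bool:
        return self.alt.endswith(">>")

    @property
    def is_sequence_variant(self) -> bool:
        """True for SNV/indel records with plain ACGT alleles."""
        return bool(_DNA_RE.match(self.ref)) and bool(_DNA_RE.match(self.alt))

    @property
    def is_genotypable(self) -> bool:
        """Variants called from reads by the amplicon genotyper."""
        return self.is_sequence_variant and not self.is_repeat_expansion


@dataclass(frozen=True)
class AmpliconTarget:
    """A local amplicon reference carrying one or more panel variants."""

    amplicon_id: str
    target_variant_ids: tuple[str, ...]
    local_ref_seq: str
    variant_offsets: Mapping[str, int]  # variant_id -> 0-based offset

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.local_ref_seq):
            raise ValueError(f"{self.amplicon_id}: reference must be uppercase ACGT")
        for vid, off in self.variant_offsets.items():
            if not 0 <= off < len(self.local_ref_seq):
                raise ValueError(f"{self.amplicon_id}: offset of {vid} outside amplicon")

    def __len__(self) -> int:
        return len(self.local_ref_seq)


@dataclass(frozen=True)
class CohortTableRow:
    """One (variant, population) cell of a published frequency table.

    ``carriers``/``n`` are ``None`` when the table prints "ND" (no data).
    ``percent_printed`` is the percent exactly as printed, as a Decimal.
    """

    variant_id: str
    population: str
    carriers: int | None
    n: int | None
    percent_printed: Decimal | None = None

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if (self.carriers is None) != (self.n is None):
            raise ValueError(f"{self.variant_id}: carriers and n must both be present or ND")
        if self.n is not None:
            if self.n <= 0:
                raise ValueError(f"{self.variant_id}: n must be positive")
            if self.carriers < 0 or self.carriers > self.n:
                raise ValueError(
                    f"{self.variant_id}: carriers {self.carriers} outside 0..{self.n}"
                )

    @property
    def is_missing(self) -> bool:
        return self.n is None


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def _parse_int(value: str, what: str, line: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValueError(f"line {line}: malformed {what}: {value!r}") from None


def _normalize_chrom(chrom: str) -> str:
    chrom = chrom.strip()
    return chrom if chrom.lower().startswith("chr") else f"chr{chrom}"


def load_panel_manifest(path: str | Path) -> list[VariantDef]:
    """Load a panel manifest TSV into validated :class:`VariantDef` records.

    Raises ``ValueError`` naming the offending line for malformed rows and
    for duplicate ``variant_id`` entries. Chromosome labels are normalized
    to the ``chrN`` form.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing columns {missing}")
    variants: list[VariantDef] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line = int(idx) + 2  # 1-based, after the header
        vid = row["variant_id"].strip()
        if not vid:
            raise ValueError(f"line {line}: empty variant_id")
        if vid in seen:
            raise ValueError(f"line {line}: duplicate variant_id {vid!r}")
        seen.add(vid)
        ref = row["ref"].strip()
        alt = row["alt"].strip()
        end = row["end_hg38"].strip()
        try:
            variants.append(
                VariantDef(
                    variant_id=vid,
                    chrom=_normalize_chrom(row["chrom"]),
                    pos_hg38=_parse_int(row["pos_hg38"], "pos_hg38", line),
                    ref="" if ref.upper() == "N/A" else ref,
                    alt="" if alt.upper() == "N/A" else alt,
                    gene=row["gene"].strip(),
                    omim=row["omim"].strip(),
                    hgvs_c=row["hgvs_c"].strip(),
                    hgvs_p=row["hgvs_p"].strip(),
                    phenotype=row["phenotype"].strip(),
                    category=int(row["category"]) if row["category"].strip() else None,
                    rsid=row["rsid"].strip(),
                    end_hg38=_parse_int(end, "end_hg38", line) if end else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {line}: {exc}") from None
    return variants


def write_panel_manifest(variants: Sequence[VariantDef], path: str | Path) -> None:
    """Write a manifest TSV that :func:`load_panel_manifest` round-trips."""
    rows = []
    for v in variants:
        rows.append(
            {
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos_hg38": v.pos_hg38,
                "end_hg38": "" if v.end_hg38 is None else v.end_hg38,
                "rsid": v.rsid,
                "ref": v.ref or "N/A",
                "alt": v.alt or "N/A",
                "gene": v.gene,
                "omim": v.omim,
                "hgvs_c": v.hgvs_c,
                "hgvs_p": v.hgvs_p,
                "phenotype": v.phenotype,
                "category": "" if v.category is None else v.category,
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

def parse_count(cell: str) -> tuple[int, int] | None:
    """Parse a "k/n" count cell; "ND" (no data) returns ``None``."""
    cell = cell.strip()
    if cell.upper() == "ND":
        return None
    m = re.fullmatch(r"(\d+)\s*/\s*(\d+)", cell)
    if not m:
        raise ValueError(f"malformed count cell {cell!r} (expected 'k/n' or 'ND')")
    return int(m.group(1)), int(m.group(2))


def load_cohort_table(
    path: str | Path,
    population_columns: Mapping[str, tuple[str, str]],
) -> list[CohortTableRow]:
    """Load a published frequency table into :class:`CohortTableRow` entries.

    ``population_columns`` maps a population label to its (count, percent)
    column pair. A printed percent more than 0.005 away from
    ``100*carriers/n`` triggers a warning (the tables are transcriptions;
    a true mismatch would point at a transcription error), while ``k > n``
    is a hard validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows: list[CohortTableRow] = []
    for idx, rec in df.iterrows():
        line = int(idx) + 2
        vid = rec["variant_id"].strip()
        for population, (count_col, pct_col) in population_columns.items():
            try:
                parsed = parse_count(rec[count_col])
            except ValueError as exc:
                raise ValueError(f"line {line}: {exc}") from None
            pct_cell = rec[pct_col].strip() if pct_col in rec else ""
            percent = None
            if pct_cell and pct_cell.upper() != "ND":
                percent = Decimal(pct_cell)
            if parsed is None:
                row = CohortTableRow(vid, population, None, None, percent)
            else:
                carriers, n = parsed
                try:
                    row = CohortTableRow(vid, population, carriers, n, percent)
                except ValueError as exc:
                    raise ValueError(f"line {line}: {exc}") from None
                if percent is not None:
                    exact = Decimal(100) * Decimal(carriers) / Decimal(n)
                    if abs(exact - percent) > Decimal("0.005"):
                        warnings.warn(
                            f"{vid} [{population}]: printed {percent}% differs from "
                            f"100*{carriers}/{n} by more than 0.005",
                            stacklevel=2,
                        )
            rows.append(row)
    return rows


def fixture_path(name: str) -> Path:
    """Path of a packaged data fixture."""
    return Path(resources.files("ampliscreen.data") / name)


def fixture_sha256(name: str) -> str:
    return hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()


def default_panel() -> list[VariantDef]:
    """The 40-variant screened panel shipped with the package."""
    return load_panel_manifest(fixture_path("panel_manifest.tsv"))


def load_table1() -> list[CohortTableRow]:
    """The 33-variant table observed in the small 100%-ancestry cohort."""
    return load_cohort_table(fixture_path("table1.tsv"), TABLE1_COLUMNS)


def load_table3() -> list[CohortTableRow]:
    """The 22-variant table screened in the large mixed cohorts."""
    return load_cohort_table(fixture_path("table3.tsv"), TABLE3_COLUMNS)


# ---------------------------------------------------------------------------
# Synthetic amplicon references
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAA_RUN = re.compile("GAAGAAGAAG")  # any GAA-motif run >= 4 triplets contains this


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    while True:
        seq = rng.choice(_BASES, size=length).tobytes().decode()
        # keep amplicons free of GAA-repeat runs so repeat-read triage cannot
        # mistake an SNV amplicon read for the repeat locus
        if not _GAA_RUN.search(seq):
            return seq


def build_amplicons(
    variants: Iterable[VariantDef],
    amplicon_len: int = 400,
    variant_offset: int = 189,
) -> list[AmpliconTarget]:
    """Build one synthetic amplicon reference per genotypable variant.

    The multiplex assay's true primer coordinates are not public, so each
    SNV/indel gets its own randomly generated local reference with the ref
    allele embedded at ``variant_offset``; the variant is central enough
    that every simulated full-length read covers it. Sequences are fixed by
    an internal seed and therefore identical across runs, like a reference
    genome. Repeat-expansion and region-deletion records get no amplicon.
    """
    amplicons = []
    for i, v in enumerate(sorted(variants, key=lambda v: v.variant_id)):
        if not v.is_genotypable:
            continue
        if variant_offset + len(v.ref) >= amplicon_len:
            raise ValueError(f"{v.variant_id}: ref allele does not fit the amplicon")
        rng = np.random.default_rng(np.random.SeedSequence([_REFERENCE_SEED, i]))
        seq = _random_sequence(rng, amplicon_len)
        seq = seq[:variant_offset] + v.ref + seq[variant_offset + len(v.ref):]
        if _GAA_RUN.search(seq):  # ref allele insertion could complete a run
            seq = _random_sequence(rng, variant_offset) + v.ref + seq[variant_offset + len(v.ref):]
        amplicons.append(
            AmpliconTarget(
                amplicon_id=f"amp_{v.variant_id}",
                target_variant_ids=(v.variant_id,),
                local_ref_seq=seq,
                variant_offsets={v.variant_id: variant_offset},
            )
        )
    return amplicons


def alt_haplotype(amplicon: AmpliconTarget, variant: VariantDef) -> str:
    """Amplicon sequence with the variant's alt allele substituted."""
    off = amplicon.variant_offsets[variant.variant_id]
    ref = amplicon.local_ref_seq
    if ref[off:off + len(variant.ref)] != variant.ref:
        raise ValueError(f"{variant.variant_id}: ref allele absent at offset {off}")
    return ref[:off] + variant.alt + ref[off + len(variant.ref):]
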