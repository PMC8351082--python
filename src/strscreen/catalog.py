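"""Disease-STR locus catalog: loading, validation, and allelic classification.

A locus catalog describes the known pathogenic short-tandem-repeat loci that
a screening run interrogates: reference coordinates of the repeat tract,
repeat-unit motif, inheritance mode, and the repeat-count ranges that define
the clinically recognised allelic classes (normal, intermediate, premutation,
borderline, and full-mutation, the last optionally subdivided into reduced-
and full-penetrance bands).

Threshold convention
--------------------
Clinical sources state full-mutation boundaries inconsistently ("> 200
repeats" vs a printed threshold column of 200).  To remove any off-by-one
ambiguity, ``fm_threshold`` here is always the *smallest repeat count
classified full-mutation* (>= semantics).  Where the conventional printed
figure differs (e.g. FMR1, whose "> 200" rule becomes ``fm_threshold=201``),
the printed figure is preserved in ``fm_threshold_printed``.  The sensitised
screening thresholds for the GC-rich fragile-X loci follow the same encoding
(FMR1: printed 54 / effective 55; FMR2: printed 60 / effective 61).

Coordinates are stored 1-based inclusive (the convention of the genotyper
region strings, e.g. ``13:70713516-70713560`` for ATXN8); converters to
half-open 0-based intervals are provided at the I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "AllelicClass",
    "CatalogError",
    "LocusDefinition",
    "SampleClassification",
    "CLASS_RANK",
    "CLASS_SHORT",
    "classify_allele",
    "classify_sample",
    "default_catalog",
    "load_catalog",
    "save_catalog",
    "catalog_by_id",
    "to_eh_variant_catalog",
    "from_eh_variant_catalog",
    "to_gangstr_bed",
    "from_gangstr_bed",
]

INHERITANCE_MODES = ("autosomal_dominant", "autosomal_recessive", "X_linked")

#: Ordering of class labels by severity; borderline and full_mutation share
#: the top rank (a borderline allele sits inside the full-mutation region,
#: between the reduced- and full-penetrance bands).
CLASS_RANK = {
    "normal": 0,
    "intermediate": 1,
    "premutation": 2,
    "borderline": 3,
    "full_mutation": 3,
}

#: Two-letter codes used in zygosity summaries (e.g. "NL/FM").
CLASS_SHORT = {
    "normal": "NL",
    "intermediate": "IM",
    "premutation": "PM",
    "borderline": "BL",
    "full_mutation": "FM",
}


class CatalogError(ValueError):
    """Raised for schema or invariant violations in a locus catalog."""


@dataclass(frozen=True)
class LocusDefinition:
    """One disease STR locus and its allelic-class geometry.

    Parameters
    ----------
    locus_id
        Gene symbol, unique within a catalog.
    chrom, start, end
        1-based inclusive reference coordinates (hg19) of the repeat tract.
    motif
        Repeat-unit sequence, 1-6 bp.
    inheritance
        ``autosomal_dominant``, ``autosomal_recessive`` or ``X_linked``.
    normal_max
        Largest repeat count regarded as normal (informational; any count
        not captured by a higher-ranked range falls back to normal).
    fm_threshold
        Smallest repeat count classified full-mutation (>= semantics).
    fm_threshold_printed
        The conventional printed threshold figure, where it differs from
        the effective minimum (metadata only).
    lowered_threshold
        Effective full-mutation minimum in sensitised (``lowered``) screening
        mode; ``lowered_threshold_printed`` keeps the conventional figure.
    off_target_sites
        ``(chrom, start, end)`` intervals where mismapped in-repeat reads
        accumulate.  Carried as opaque metadata for external genotypers.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    motif: str
    inheritance: str
    normal_max: int
    fm_threshold: int
    locus_structure: Optional[str] = None
    intermediate_range: Optional[tuple[int, int]] = None
    premutation_range: Optional[tuple[int, int]] = None
    reduced_penetrance_range: Optional[tuple[int, int]] = None
    borderline_range: Optional[tuple[int, int]] = None
    full_penetrance_min: Optional[int] = None
    fm_threshold_printed: Optional[int] = None
    lowered_threshold: Optional[int] = None
    lowered_threshold_printed: Optional[int] = None
    off_target_sites: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        errors = []
        if self.start > self.end:
            errors.append(f"start {self.start} > end {self.end}")
        if not (1 <= len(self.motif) <= 6):
            errors.append(f"motif length {len(self.motif)} outside 1..6")
        if self.inheritance not in INHERITANCE_MODES:
            errors.append(f"unknown inheritance {self.inheritance!r}")
        if self.fm_threshold <= self.normal_max:
            errors.append(
                f"fm_threshold {self.fm_threshold} must exceed "
                f"normal_max {self.normal_max}"
            )
        for name in ("intermediate_range", "premutation_range",
                     "reduced_penetrance_range", "borderline_range"):
            rng = getattr(self, name)
            if rng is not None and rng[0] > rng[1]:
                errors.append(f"{name} [{rng[0]}, {rng[1]}] is inverted")
        # Non-FM class ranges must be ordered below the full-mutation region
        # and each other: normal < intermediate < premutation < full-mutation.
        prev_hi, prev_name = self.normal_max, "normal_max"
        for name in ("intermediate_range", "premutation_range"):
            rng = getattr(self, name)
            if rng is None:
                continue
            if rng[0] <= prev_hi:
                errors.append(f"{name} overlaps or precedes {prev_name}")
            prev_hi, prev_name = rng[1], name
        if prev_hi >= self.fm_threshold:
            errors.append(f"{prev_name} reaches into the full-mutation region")
        if (self.reduced_penetrance_range is not None
                and self.full_penetrance_min is not None
                and self.reduced_penetrance_range[1] >= self.full_penetrance_min):
            errors.append(
                "reduced_penetrance_range must precede full_penetrance_min")
        if (self.lowered_threshold is not None
                and self.lowered_threshold > self.fm_threshold):
            errors.append("lowered_threshold exceeds fm_threshold")
        if errors:
            raise CatalogError(
                f"invalid locus {self.locus_id!r}: " + "; ".join(errors))

    @property
    def region(self) -> str:
        """1-based inclusive region string, e.g. ``13:70713516-70713560``."""
        chrom = self.chrom.removeprefix("chr")
        return f"{chrom}:{self.start}-{self.end}"

    def interval0(self) -> tuple[str, int, int]:
        """Half-open 0-based interval for BED-style interfaces."""
        return self.chrom, self.start - 1, self.end

    def effective_fm_min(self, mode: str = "default") -> int:
        """Smallest repeat count flagged full-mutation under *mode*."""
        if mode == "lowered" and self.lowered_threshold is not None:
            return self.lowered_threshold
        if mode not in ("default", "lowered"):
            raise ValueError(f"unknown mode {mode!r}")
        return self.fm_threshold


@dataclass(frozen=True)
class AllelicClass:
    """Classification of a single allele at one locus."""

    label: str
    repeat_count: int
    penetrance: Optional[str] = None  # "reduced" | "full", FM only

    def __post_init__(self) -> None:
        if self.label not in CLASS_RANK:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.penetrance is not None and self.label != "full_mutation":
            raise ValueError("penetrance only applies to full_mutation")

    @property
    def short(self) -> str:
        return CLASS_SHORT[self.label]

    @property
    def rank(self) -> int:
        return CLASS_RANK[self.label]


@dataclass(frozen=True)
class SampleClassification:
    """Per-sample (one- or two-allele) classification at one locus."""

    locus_id: str
    alleles: tuple[AllelicClass, ...]
    zygosity: str       # e.g. "NL/FM", "FM/FM", or "FM" when hemizygous
    flag: bool          # True when at least one allele is full-mutation

    @property
    def max_class(self) -> AllelicClass:
        return max(self.alleles, key=lambda a: (a.rank, a.repeat_count))


def classify_allele(locus: LocusDefinition, repeat_count: int,
                    mode: str = "default") -> AllelicClass:
    """Classify one allele's repeat count under the locus's class geometry.

    The full-mutation region starts at ``effective_fm_min(mode)``; within it,
    counts inside ``borderline_range`` are labelled ``borderline`` and the
    penetrance bands annotate the remainder.  Below it, the premutation and
    intermediate ranges apply in decreasing order of severity, with normal as
    the fallback.  The mapping is exhaustive and mutually exclusive over the
    non-negative integers.
    """
    if repeat_count < 0:
        raise ValueError(f"negative repeat count {repeat_count}")
    if repeat_count >= locus.effective_fm_min(mode):
        rng = locus.borderline_range
        if rng is not None and rng[0] <= repeat_count <= rng[1]:
            return AllelicClass("borderline", repeat_count)
        penetrance = None
        if (locus.full_penetrance_min is not None
                and repeat_count >= locus.full_penetrance_min):
            penetrance = "full"
        elif (locus.reduced_penetrance_range is not None
              and locus.reduced_penetrance_range[0] <= repeat_count
              <= locus.reduced_penetrance_range[1]):
            penetrance = "reduced"
        return AllelicClass("full_mutation", repeat_count, penetrance)
    for label, rng in (("premutation", locus.premutation_range),
                       ("intermediate", locus.intermediate_range)):
        if rng is not None and rng[0] <= repeat_count <= rng[1]:
            return AllelicClass(label, repeat_count)
    return AllelicClass("normal", repeat_count)


def classify_sample(locus: LocusDefinition,
                    genotype: Sequence[int],
                    mode: str = "default") -> SampleClassification:
    """Classify a one- or two-allele genotype and summarise its zygosity.

    The sample-level flag is positive when at least one allele is
    full-mutation, mirroring how genotyper calls are binarized.
    """
    if not 1 <= len(genotype) <= 2:
        raise ValueError(
            f"genotype must have 1 or 2 alleles, got {len(genotype)}")
    alleles = tuple(classify_allele(locus, c, mode) for c in genotype)
    ordered = sorted(alleles, key=lambda a: (a.rank, a.repeat_count))
    zygosity = "/".join(a.short for a in ordered)
    flag = any(a.label == "full_mutation" for a in alleles)
    return SampleClassification(locus.locus_id, alleles, zygosity, flag)


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------

_RANGE_FIELDS = ("intermediate_range", "premutation_range",
                 "reduced_penetrance_range", "borderline_range")


def _locus_from_record(rec: dict) -> LocusDefinition:
    rec = dict(rec)
    for name in _RANGE_FIELDS:
        if rec.get(name) is not None:
            lo, hi = rec[name]
            rec[name] = (int(lo), int(hi))
    ots = rec.get("off_target_sites") or ()
    rec["off_target_sites"] = tuple(
        (str(c), int(s), int(e)) for c, s, e in ots)
    try:
        return LocusDefinition(**rec)
    except TypeError as exc:
        raise CatalogError(f"malformed locus record: {exc}") from exc


def load_catalog(path: str | Path | None = None) -> list[LocusDefinition]:
    """Load a locus catalog from a YAML file (the packaged default if None).

    Raises
    ------
    CatalogError
        On duplicate ``locus_id`` (named in the message) or any violated
        range-ordering invariant (listing the offending field).
    """
    if path is None:
        text = (resources.files("strscreen.data") / "catalog.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        return []
    records = doc.get("loci", doc) if isinstance(doc, dict) else doc
    if not records:
        return []
    loci = [_locus_from_record(rec) for rec in records]
    seen: set[str] = set()
    for locus in loci:
        if locus.locus_id in seen:
            raise CatalogError(f"duplicate locus_id {locus.locus_id!r}")
        seen.add(locus.locus_id)
    return loci


def save_catalog(loci: Iterable[LocusDefinition], path: str | Path) -> None:
    """Write a catalog back to YAML (round-trips with :func:`load_catalog`)."""
    records = []
    for locus in loci:
        rec: dict = {
            "locus_id": locus.locus_id,
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "motif": locus.motif,
            "inheritance": locus.inheritance,
            "normal_max": locus.normal_max,
            "fm_threshold": locus.fm_threshold,
        }
        for name in ("locus_structure", "fm_threshold_printed",
                     "lowered_threshold", "lowered_threshold_printed",
                     "full_penetrance_min"):
            val = getattr(locus, name)
            if val is not None:
                rec[name] = val
        for name in _RANGE_FIELDS:
            rng = getattr(locus, name)
            if rng is not None:
                rec[name] = list(rng)
        if locus.off_target_sites:
            rec["off_target_sites"] = [list(t) for t in locus.off_target_sites]
        records.append(rec)
    Path(path).write_text(yaml.safe_dump({"loci": records}, sort_keys=False))


def default_catalog() -> list[LocusDefinition]:
    """The packaged catalog: 10 benchmark loci plus ATXN2 and ATXN8."""
    return load_catalog(None)


def catalog_by_id(loci: Iterable[LocusDefinition]) -> dict[str, LocusDefinition]:
    return {locus.locus_id: locus for locus in loci}


# ---------------------------------------------------------------------------
# Converters to external catalog dialects
# ---------------------------------------------------------------------------

def to_eh_variant_catalog(loci: Iterable[LocusDefinition]) -> list[dict]:
    """ExpansionHunter-style variant-catalog JSON records."""
    records = []
    for locus in loci:
        rec = {
            "VariantType": "Repeat",
            "LocusId": locus.locus_id,
            "LocusStructure": locus.locus_structure or f"({locus.motif})*",
            "ReferenceRegion": locus.region,
        }
        if locus.off_target_sites:
            rec["OfftargetRegions"] = [
                f"{c.removeprefix('chr')}:{s}-{e}"
                for c, s, e in locus.off_target_sites]
        records.append(rec)
    return records


def from_eh_variant_catalog(records: list[dict] | str | Path,
                            base: Iterable[LocusDefinition] | None = None,
                            ) -> list[LocusDefinition]:
    """Merge EH-style records onto a base catalog (default: packaged).

    The EH dialect carries coordinates/structure only, so class thresholds
    come from the base catalog; records for unknown loci are rejected.
    """
    if not isinstance(records, list):
        records = json.loads(Path(records).read_text())
    by_id = catalog_by_id(base if base is not None else default_catalog())
    out = []
    for rec in records:
        locus_id = rec["LocusId"]
        if locus_id not in by_id:
            raise CatalogError(
                f"EH record {locus_id!r} has no thresholds in the base catalog")
        region = rec["ReferenceRegion"]
        chrom, span = region.split(":")
        start, end = (int(x) for x in span.split("-"))
        ots = tuple(
            (r.split(":")[0], int(r.split(":")[1].split("-")[0]),
             int(r.split(":")[1].split("-")[1]))
            for r in rec.get("OfftargetRegions", ()))
        out.append(replace(
            by_id[locus_id],
            chrom=chrom if chrom.startswith("chr") else f"chr{chrom}",
            start=start, end=end,
            locus_structure=rec.get("LocusStructure"),
            off_target_sites=ots))
    return out


def to_gangstr_bed(loci: Iterable[LocusDefinition]) -> str:
    """GangSTR-style region lines (1-based start, tab-separated).

    Columns: chrom, start, end, motif length, motif, then an optional
    off-target column of comma-joined intervals.
    """
    lines = []
    for locus in loci:
        cols = [locus.chrom, str(locus.start), str(locus.end),
                str(len(locus.motif)), locus.motif]
        if locus.off_target_sites:
            cols.append(",".join(
                f"{c}:{s}-{e}" for c, s, e in locus.off_target_sites))
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def from_gangstr_bed(text: str, base: Iterable[LocusDefinition] | None = None,
                     ) -> list[LocusDefinition]:
    """Parse GangSTR-style region lines, matching loci by coordinates/motif.

    Lines are matched to the base catalog by motif and chromosome; thresholds
    are taken from the matched base locus, coordinates and off-target sites
    from the line.
    """
    base_loci = list(base if base is not None else default_catalog())
    out = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 5:
            raise CatalogError(f"line {lineno}: expected >=5 columns")
        chrom, start, end, _, motif = cols[:5]
        match = next(
            (l for l in base_loci if l.chrom == chrom and l.motif == motif),
            None)
        if match is None:
            raise CatalogError(
                f"line {lineno}: no base locus with chrom {chrom} motif {motif}")
        ots: tuple[tuple[str, int, int], ...] = ()
        if len(cols) > 5 and cols[5]:
            ots = tuple(
                (r.split(":")[0], int(r.split(":")[1].split("-")[0]),
                 int(r.split(":")[1].split("-")[1]))
                for r in cols[5].split(","))
        out.append(replace(match, start=int(start), end=int(end),
                           off_target_sites=ots))
    return out
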