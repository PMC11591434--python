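"""Shared data model and VCF / popmap I/O.

The whole pipeline operates on a :class:`GenotypeMatrix`: a samples x loci
table of diploid alternate-allele dosages (0, 1, 2 or missing) plus locus and
sample metadata.  Phase is deliberately discarded on input — no downstream
stage uses it.  Coordinates are 1-based (VCF convention) throughout; BED
exports convert to 0-based half-open at the single point of export.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rohsignal")

#: Sentinel dosage for a missing (or half-missing) genotype call.
MISSING: int = -1

LOCUS_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class VCFParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class PopmapError(ValueError):
    """Raised for malformed or conflicting population-map files."""


@dataclass(frozen=True)
class LocusInfo:
    """A single bi-allelic SNP locus."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"locus {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"locus {self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class SampleInfo:
    """One diploid individual and its population label."""

    sample_id: str
    population: str = ""


class PopulationMap(dict):
    """Mapping ``sample_id -> population label``."""

    @property
    def populations(self) -> list[str]:
        """Distinct population labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.items() if p == population]


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of alternate-allele dosages.

    Parameters
    ----------
    samples
        DataFrame with columns ``sample_id`` and ``population``.
    loci
        DataFrame with columns ``chrom, pos, id, ref, alt``; within each
        chromosome positions must be strictly increasing.
    calls
        ``int8`` array of shape ``(n_samples, n_loci)`` with entries in
        ``{0, 1, 2, MISSING}``.
    """

    samples: pd.DataFrame
    loci: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.samples = self.samples.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid dosage values {bad.tolist()}")
        if self.samples["sample_id"].duplicated().any():
            dups = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        for chrom, grp in self.loci.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions on {chrom} are not strictly increasing")

    # -- subsetting ----------------------------------------------------------

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.samples.iloc[idx], self.loci, self.calls[idx, :])

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.samples, self.loci.iloc[idx], self.calls[:, idx])

    def sample_indices(self, population: str) -> np.ndarray:
        """Row indices of the samples belonging to *population*."""
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown or empty population {population!r}")
        return idx

    def attach_popmap(self, popmap: PopulationMap) -> "GenotypeMatrix":
        """Return a copy restricted to mapped samples, with populations set.

        Samples absent from the map are dropped with a warning, per the
        contract that every sample is either mapped or explicitly discarded.
        """
        known = self.samples["sample_id"].isin(popmap.keys())
        n_drop = int((~known).sum())
        if n_drop:
            dropped = self.samples.loc[~known, "sample_id"].tolist()
            logger.warning("dropping %d unmapped samples: %s", n_drop, dropped)
        samples = self.samples[known].copy()
        samples["population"] = samples["sample_id"].map(popmap)
        return GenotypeMatrix(samples, self.loci, self.calls[known.to_numpy(), :])


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------


def read_vcf(
    path,
    autosomes=None,
    strict_biallelic: bool = True,
) -> GenotypeMatrix:
    """Read a VCF 4.x file (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF file path.
    autosomes
        Optional chromosome whitelist; records on other chromosomes are
        dropped.  Labels are compared as opaque strings.
    strict_biallelic
        When true (default), records with zero or more than one ALT allele
        and records whose alleles are not single bases (indels) are dropped
        and the drop counted in the log.

    Notes
    -----
    Genotypes are collapsed to alternate-allele dosage; phasing is ignored.
    Half-missing calls (one known allele) are mapped to :data:`MISSING`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise VCFParseError(f"VCF {path} contains no samples")
    if autosomes is not None:
        autosomes = {str(c) for c in autosomes}

    rows: list[tuple] = []
    dosages: list[np.ndarray] = []
    n_multi = n_indel = n_offchrom = 0
    for rec in vcf:
        if autosomes is not None and str(rec.CHROM) not in autosomes:
            n_offchrom += 1
            continue
        alts = rec.ALT
        if strict_biallelic:
            if len(alts) != 1:
                n_multi += 1
                continue
            if len(rec.REF) != 1 or len(alts[0]) != 1:
                n_indel += 1
                continue
        elif not alts:
            n_multi += 1
            continue
        gt = np.asarray(rec.genotype.array())  # (n_samples, ploidy+1); last col phase
        alleles = gt[:, :2]
        dose = (alleles > 0).sum(axis=1).astype(np.int8)
        dose[(alleles < 0).any(axis=1)] = MISSING
        rows.append((str(rec.CHROM), rec.POS, rec.ID or f"{rec.CHROM}_{rec.POS}",
                     rec.REF, alts[0]))
        dosages.append(dose)
    vcf.close()

    if n_multi or n_indel or n_offchrom:
        logger.info(
            "read_vcf: dropped %d multi-allelic, %d indel, %d off-whitelist records",
            n_multi, n_indel, n_offchrom,
        )
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    calls = (
        np.stack(dosages, axis=1)
        if dosages
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population": ""})
    return GenotypeMatrix(samples, loci, calls)


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write *gm* as a minimal VCF 4.2 with a GT field only."""
    chrom_order: dict[str, None] = {}
    for c in gm.loci["chrom"]:
        chrom_order.setdefault(c, None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohsignal\n")
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        calls = gm.calls
        for j, loc in enumerate(gm.loci.itertuples(index=False)):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in calls[:, j])
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{loc.id}\t{loc.ref}\t{loc.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------


def read_popmap(path) -> PopulationMap:
    """Read a two-column (sample, population) map; tab or whitespace delimited.

    Raises
    ------
    PopmapError
        On an empty file, a malformed row, or a sample listed twice
        (with the same or a different population).
    """
    pm = PopulationMap()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise PopmapError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sample, pop = parts[0].strip(), parts[1].strip()
            if sample in pm:
                if pm[sample] != pop:
                    raise PopmapError(
                        f"{path}:{lineno}: sample {sample!r} mapped to both "
                        f"{pm[sample]!r} and {pop!r}"
                    )
                raise PopmapError(f"{path}:{lineno}: duplicate sample row {sample!r}")
            pm[sample] = pop
    if not pm:
        raise PopmapError(f"population map {path} is empty")
    return pm


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def setup_logging(level=logging.INFO) -> None:
    """Route package logs to standard error (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
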