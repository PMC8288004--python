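"""Genotype matrix container, SNP-table/VCF I/O, and quality-control filters.

Genotypes are biallelic allele counts: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, -1 = missing.

The QC stage applies the standard reduced-representation filters in a fixed
order: (1) locus missingness < 5%, (2) technical reproducibility > 0.98,
(3) minor allele frequency > 5% (over non-missing calls), then
(4) individual missingness < 20%, and finally random thinning to one SNP per
sequenced fragment so retained loci are not trivially linked.  All thresholds
are strict inequalities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "GenotypeMatrix", "QcReport", "read_snp_table", "write_snp_table",
    "read_samples_csv", "filter_loci", "filter_individuals",
    "thin_one_per_fragment", "global_missing_rate", "run_qc",
    "pop_allele_counts",
]


@dataclass
class GenotypeMatrix:
    """individuals x loci allele counts with sample and locus metadata.

    counts : int array (n_samples, n_loci) over {0,1,2,-1}.
    samples : DataFrame with columns sample_id, population, lon, lat.
    loci : DataFrame with columns locus_id, fragment_id, reproducibility.
    """

    counts: np.ndarray = field(repr=False)
    samples: pd.DataFrame = field(repr=False)
    loci: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample records for {n} matrix rows")
        if len(self.loci) != m:
            raise ValueError(f"{len(self.loci)} locus records for {m} matrix columns")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("duplicate locus ids")
        if self.loci["fragment_id"].isna().any():
            raise ValueError("every locus needs a fragment_id")
        bad = ~np.isin(self.counts, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.counts[bad])}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_loci(self) -> int:
        return self.counts.shape[1]

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def missing_mask(self) -> np.ndarray:
        return self.counts == MISSING

    def locus_missing_frac(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_missing_frac(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per locus over non-missing calls."""
        c = np.ma.masked_equal(self.counts, MISSING)
        p = c.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(p, 1 - p)

    def subset_loci(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(counts=self.counts[:, keep],
                              samples=self.samples.reset_index(drop=True),
                              loci=self.loci.iloc[keep].reset_index(drop=True))

    def subset_samples(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(counts=self.counts[keep, :],
                              samples=self.samples.iloc[keep].reset_index(drop=True),
                              loci=self.loci.reset_index(drop=True))

    def loci_by_ids(self, ids) -> "GenotypeMatrix":
        idx = self.loci.set_index("locus_id").index
        pos = idx.get_indexer(list(ids))
        if (pos < 0).any():
            raise KeyError("unknown locus ids requested")
        return self.subset_loci(pos)


# ------------------------------------------------------------------------- I/O
def write_snp_table(g: GenotypeMatrix, path) -> None:
    """SNP-table CSV: header of sample ids; one row per locus with
    locus_id, fragment_id, reproducibility, then counts ('-' = missing)."""
    with open(path, "w") as fh:
        fh.write("locus_id,fragment_id,reproducibility,"
                 + ",".join(g.samples["sample_id"]) + "\n")
        for j in range(g.n_loci):
            row = g.loci.iloc[j]
            vals = ["-" if v == MISSING else str(int(v)) for v in g.counts[:, j]]
            fh.write(f"{row.locus_id},{row.fragment_id},{float(row.reproducibility)!r},"
                     + ",".join(vals) + "\n")


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"sample_id", "population", "lon", "lat"}
    if not need.issubset(df.columns):
        raise ValueError(f"sample metadata must have columns {sorted(need)}")
    return df


def _read_snp_csv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header[:3] != ["locus_id", "fragment_id", "reproducibility"]:
            raise ValueError(f"{path}: malformed header {header[:3]}")
        sample_ids = header[3:]
        counts_rows, loci_rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != 3 + len(sample_ids):
                raise ValueError(f"{path}: line {ln}: expected "
                                 f"{3 + len(sample_ids)} fields, got {len(parts)}")
            locus_id, frag, repro = parts[:3]
            try:
                vals = [MISSING if v == "-" else int(v) for v in parts[3:]]
                repro_f = float(repro) if repro != "" else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from exc
            loci_rows.append((locus_id, frag if frag else locus_id, repro_f))
            counts_rows.append(vals)
    counts = np.array(counts_rows, dtype=np.int16).T
    samples = pd.DataFrame({"sample_id": sample_ids,
                            "population": "", "lon": np.nan, "lat": np.nan})
    loci = pd.DataFrame(loci_rows, columns=["locus_id", "fragment_id",
                                            "reproducibility"])
    return GenotypeMatrix(counts=counts, samples=samples, loci=loci)


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    counts_rows, loci_rows = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        row = np.empty(len(sample_ids), dtype=np.int16)
        for i, gt in enumerate(v.genotypes):
            a = gt[:-1]  # drop phasing flag
            row[i] = MISSING if any(x < 0 for x in a) else int(sum(x > 0 for x in a))
        locus_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        loci_rows.append((locus_id, locus_id, 1.0))
        counts_rows.append(row)
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)
    counts = np.array(counts_rows, dtype=np.int16).T
    samples = pd.DataFrame({"sample_id": sample_ids,
                            "population": "", "lon": np.nan, "lat": np.nan})
    loci = pd.DataFrame(loci_rows, columns=["locus_id", "fragment_id",
                                            "reproducibility"])
    return GenotypeMatrix(counts=counts, samples=samples, loci=loci)


def read_snp_table(path, dialect="snp-csv") -> GenotypeMatrix:
    """Read genotypes from the SNP-table CSV dialect or a (plain-text) VCF.

    Absent reproducibility scores default to 1.0 and absent fragment ids to
    the locus id.  Sample metadata (population, coordinates) is attached
    separately via :func:`attach_sample_metadata`.
    """
    if dialect == "snp-csv":
        return _read_snp_csv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def attach_sample_metadata(g: GenotypeMatrix, samples: pd.DataFrame) -> GenotypeMatrix:
    meta = samples.set_index("sample_id")
    missing = set(g.samples["sample_id"]) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    new = meta.loc[g.samples["sample_id"]].reset_index()
    return GenotypeMatrix(counts=g.counts, samples=new, loci=g.loci)


# -------------------------------------------------------------------------- QC
@dataclass
class QcReport:
    n_loci_in: int
    n_samples_in: int
    loci_removed: dict[str, int]
    individuals_removed: list[str]
    n_fragments: int
    n_loci_out: int
    n_samples_out: int
    global_missing_after: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def filter_loci(g: GenotypeMatrix, max_missing=0.05, min_repro=0.98,
                min_maf=0.05):
    """Sequential locus filters (missingness, reproducibility, MAF), strict.

    Returns (filtered matrix, per-stage removal counts).
    """
    for t in (max_missing, min_repro, min_maf):
        if not (0 <= t <= 1):
            raise ValueError("thresholds must be in [0, 1]")
    stages: dict[str, int] = {}
    keep = g.locus_missing_frac() < max_missing
    stages["missing"] = int((~keep).sum())
    g = g.subset_loci(keep)
    keep = g.loci["reproducibility"].to_numpy() > min_repro
    stages["reproducibility"] = int((~keep).sum())
    g = g.subset_loci(keep)
    keep = g.maf() > min_maf
    stages["maf"] = int((~keep).sum())
    g = g.subset_loci(keep)
    if g.n_loci == 0:
        raise ValueError("no loci left after locus filters")
    return g, stages


def filter_individuals(g: GenotypeMatrix, max_missing=0.20):
    """Retain individuals with missing fraction strictly below the threshold."""
    if not (0 <= max_missing <= 1):
        raise ValueError("threshold must be in [0, 1]")
    keep = g.sample_missing_frac() < max_missing
    removed = list(g.samples.loc[~keep, "sample_id"])
    if not keep.any():
        raise ValueError("all individuals removed by missingness filter")
    return g.subset_samples(keep), removed


def thin_one_per_fragment(g: GenotypeMatrix, seed=0) -> GenotypeMatrix:
    """Keep one uniformly chosen SNP per sequenced fragment (seeded)."""
    rng = np.random.default_rng(seed)
    frag = g.loci["fragment_id"].to_numpy()
    chosen = []
    for f in dict.fromkeys(frag):  # first-appearance order
        members = np.flatnonzero(frag == f)
        chosen.append(int(rng.choice(members)))
    return g.subset_loci(np.sort(chosen))


def global_missing_rate(g: GenotypeMatrix) -> float:
    if g.n_loci == 0 or g.n_samples == 0:
        raise ValueError("empty matrix")
    return float(g.missing_mask().mean())


def run_qc(g: GenotypeMatrix, max_locus_missing=0.05, min_repro=0.98,
           min_maf=0.05, max_ind_missing=0.20, seed=0):
    """Full QC chain: locus filters -> individual filter -> fragment thinning."""
    n_loci_in, n_samples_in = g.n_loci, g.n_samples
    g, stages = filter_loci(g, max_locus_missing, min_repro, min_maf)
    g, removed_ids = filter_individuals(g, max_ind_missing)
    g = thin_one_per_fragment(g, seed=seed)
    report = QcReport(
        n_loci_in=n_loci_in, n_samples_in=n_samples_in,
        loci_removed=stages, individuals_removed=removed_ids,
        n_fragments=g.n_loci, n_loci_out=g.n_loci, n_samples_out=g.n_samples,
        global_missing_after=global_missing_rate(g),
    )
    return g, report


# ------------------------------------------------------------- population counts
def pop_allele_counts(g: GenotypeMatrix):
    """Alternate-allele and total called-allele counts per population x locus.

    Returns (pops, alt (P x L), tot (P x L)).
    """
    pops = g.populations
    P, L = len(pops), g.n_loci
    alt = np.zeros((P, L), dtype=np.int64)
    tot = np.zeros((P, L), dtype=np.int64)
    pop_arr = g.samples["population"].to_numpy()
    for i, pop in enumerate(pops):
        block = g.counts[pop_arr == pop, :]
        called = block != MISSING
        alt[i] = np.where(called, block, 0).sum(axis=0)
        tot[i] = 2 * called.sum(axis=0)
    return pops, alt, tot
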