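"""Doubled-haploid verification: SNP heterozygosity, ploidy, outcomes.

Androgenic plants regenerated from microspores should be haploid (or doubled
haploid, i.e. fully homozygous after genome doubling).  Verification
combines flow-cytometry ploidy calls against a diploid reference peak and a
genotyping check: over the SNP positions at which the anther *donor* is
heterozygous, a true DH shows (near-)zero heterozygosity, while sexual
backcross offspring retain about half.  This module implements the donor-Het
position filter, per-sample and per-group heterozygosity summaries, the
ploidy bookkeeping and the androgenesis outcome report.

Genotype calls are coded HomRef / Het / HomAlt / Missing; missing calls are
excluded from the heterozygosity denominator and reported separately.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_TSV_CODES = {"AA": HOM_REF, "AB": HET, "BA": HET, "BB": HOM_ALT, "NA": MISSING,
              "0": HOM_REF, "1": HET, "2": HOM_ALT, ".": MISSING, "NN": MISSING}


@dataclass
class GenotypeMatrix:
    """Samples x SNP positions with calls in {HomRef, Het, HomAlt, Missing}."""

    samples: list  # sample ids
    positions: list  # SNP ids
    calls: np.ndarray  # (n_samples, n_positions) int8
    groups: dict = field(default_factory=dict)  # sample id -> {donor,BC4,DH,...}

    def __post_init__(self):
        self.calls = np.asarray(self.calls, np.int8)
        if self.calls.shape != (len(self.samples), len(self.positions)):
            raise ValueError("calls matrix shape does not match samples x positions")

    def row(self, sample_id) -> np.ndarray:
        return self.calls[self.samples.index(sample_id)]

    def subset_positions(self, position_ids) -> "GenotypeMatrix":
        idx = [self.positions.index(p) for p in position_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            positions=list(position_ids),
            calls=self.calls[:, idx],
            groups=dict(self.groups),
        )

    @classmethod
    def from_tsv(cls, path, groups=None) -> "GenotypeMatrix":
        """Read a plain matrix: rows = SNP ids, columns = samples,
        cells in {AA, AB, BB, NA} (or 0/1/2/.)."""
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        calls = np.full((df.shape[1], df.shape[0]), MISSING, np.int8)
        for j, snp in enumerate(df.index):
            for i, sample in enumerate(df.columns):
                raw = str(df.iloc[j, i]).strip().upper()
                if raw not in _TSV_CODES:
                    raise ValueError(f"unknown genotype code {raw!r} at {snp}/{sample}")
                calls[i, j] = _TSV_CODES[raw]
        return cls(
            samples=list(df.columns),
            positions=list(df.index),
            calls=calls,
            groups=dict(groups or {}),
        )

    @classmethod
    def from_vcf(cls, path, groups=None) -> "GenotypeMatrix":
        """Read diploid GT calls from a VCF (0/0 HomRef, 0/1 Het, 1/1 HomAlt)."""
        from cyvcf2 import VCF  # optional heavy import

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        positions, rows = [], []
        for var in vcf:
            positions.append(var.ID or f"{var.CHROM}:{var.POS}")
            # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            remap = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}
            rows.append([remap[int(g)] for g in var.gt_types])
        calls = np.asarray(rows, np.int8).T if rows else np.empty((len(samples), 0), np.int8)
        return cls(samples=samples, positions=positions, calls=calls,
                   groups=dict(groups or {}))


def donor_het_positions(matrix: GenotypeMatrix, donor_id):
    """SNP positions at which the donor call is heterozygous.

    Donor-missing positions are excluded; returns (positions, n_donor_missing).
    """
    donor = matrix.row(donor_id)
    keep = [p for p, c in zip(matrix.positions, donor) if c == HET]
    n_missing = int((donor == MISSING).sum())
    return keep, n_missing


def het_pct(matrix: GenotypeMatrix, sample_id, positions):
    """Heterozygosity of one sample over the given positions.

    Returns (percent to two decimals, n_missing); missing calls are dropped
    from the denominator.  All-missing samples raise.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    row = matrix.subset_positions(positions).row(sample_id)
    n_missing = int((row == MISSING).sum())
    n_called = len(positions) - n_missing
    if n_called == 0:
        raise ValueError(f"sample {sample_id}: all calls missing; heterozygosity undefined")
    pct = 100.0 * int((row == HET).sum()) / n_called
    return round(pct, 2), n_missing


@dataclass
class HetSummary:
    """Group-level heterozygosity summary (mean and range, in percent)."""

    group: str
    n_samples: int
    missing_mean: float
    missing_range: tuple[int, int]
    het_mean: float
    het_range: tuple[float, float]


def group_summary(matrix: GenotypeMatrix, positions, groups=None):
    """Per-group heterozygosity and missing-call summaries.

    ``groups`` maps sample id -> group label (defaults to matrix.groups);
    empty groups are skipped with a warning entry.  Returns
    (list of HetSummary, warnings).
    """
    groups = groups or matrix.groups
    order = []
    by_group: dict = {}
    for sid in matrix.samples:
        g = groups.get(sid)
        if g is None:
            continue
        if g not in by_group:
            by_group[g] = []
            order.append(g)
        by_group[g].append(sid)
    summaries, warnings = [], []
    for g in order:
        hets, miss = [], []
        for sid in by_group[g]:
            try:
                pct, n_missing = het_pct(matrix, sid, positions)
            except ValueError as e:
                warnings.append(str(e))
                continue
            hets.append(pct)
            miss.append(n_missing)
        if not hets:
            warnings.append(f"group {g}: no evaluable samples; omitted")
            continue
        summaries.append(
            HetSummary(
                group=g,
                n_samples=len(hets),
                missing_mean=round(float(np.mean(miss)), 2),
                missing_range=(int(min(miss)), int(max(miss))),
                het_mean=round(float(np.mean(hets)), 2),
                het_range=(round(min(hets), 2), round(max(hets), 2)),
            )
        )
    return summaries, warnings


def summaries_to_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "Accession/Offspring": s.group,
                "n": s.n_samples,
                "Missing SNPs": f"{s.missing_mean:.2f} ({s.missing_range[0]:.2f}–{s.missing_range[1]:.2f})"
                if s.n_samples > 1
                else f"{s.missing_mean:.2f}",
                "Heterozygosity (%)": f"{s.het_mean:.2f} ({s.het_range[0]:.2f}–{s.het_range[1]:.2f})"
                if s.n_samples > 1
                else f"{s.het_mean:.2f}",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ploidy bookkeeping


class Ploidy(enum.Enum):
    HAPLOID = "haploid"
    DIPLOID = "diploid"
    MIXOPLOID = "mixoploid"
    OTHER = "other"


def classify_ploidy(peak_positions, diploid_reference=50.0, tolerance=0.10) -> Ploidy:
    """Classify flow-cytometry peaks against the diploid reference.

    A single peak within ``tolerance`` (fraction of the reference) of the
    reference is diploid; within tolerance of half the reference, haploid
    (half the DNA content); one of each, mixoploid; anything else, other.
    """
    peaks = sorted(float(p) for p in peak_positions)
    if not peaks:
        raise ValueError("no peaks supplied")
    tol = tolerance * diploid_reference
    is_dip = [abs(p - diploid_reference) <= tol for p in peaks]
    is_hap = [abs(p - diploid_reference / 2.0) <= tol for p in peaks]
    has_dip = any(is_dip)
    has_hap = any(is_hap)
    unexplained = any(not (d or h) for d, h in zip(is_dip, is_hap))
    if unexplained:
        return Ploidy.OTHER
    if has_dip and has_hap:
        return Ploidy.MIXOPLOID
    if has_hap:
        return Ploidy.HAPLOID
    return Ploidy.DIPLOID


# ---------------------------------------------------------------------------
# Androgenesis outcome report


@dataclass
class AndrogenesisRecord:
    """Outcome of one (genotype, protocol, anther range) culture condition."""

    genotype: str
    protocol: str  # {E6, Cb}
    range_label: str
    n_anthers: int
    n_responding: int = 0
    response_type: str = "none"  # {embryo, callus, somatic_callus, none}
    embryos: int = 0
    acclimatized: int = 0
    haploid: int = 0  # n
    mixoploid: int = 0  # n + 2n
    diploid: int = 0  # 2n

    def __post_init__(self):
        if self.n_responding > self.n_anthers:
            raise ValueError("responding anthers exceed anthers cultured")
        if self.acclimatized > self.embryos and self.embryos > 0:
            raise ValueError("acclimatized plants exceed embryos")
        if self.haploid + self.mixoploid + self.diploid not in (0, self.acclimatized):
            raise ValueError("ploidy counts must sum to acclimatized plants")

    @property
    def response_pct(self) -> float:
        return round(100.0 * self.n_responding / self.n_anthers, 1) if self.n_anthers else 0.0

    @property
    def response_se(self) -> float:
        """Binomial standard error of the response fraction."""
        if not self.n_anthers:
            return 0.0
        p = self.n_responding / self.n_anthers
        return round(float(np.sqrt(p * (1 - p) / self.n_anthers)), 2)


def androgenesis_report(records) -> dict:
    """Totals and percentages over a set of culture records.

    Percentages are rounded to one decimal: per-record response rate (with
    binomial SE), overall acclimatization rate (plants/embryos) and the
    ploidy fractions of the acclimatized plants.
    """
    records = list(records)
    totals = {
        "anthers": sum(r.n_anthers for r in records),
        "responding": sum(r.n_responding for r in records),
        "embryos": sum(r.embryos for r in records),
        "acclimatized": sum(r.acclimatized for r in records),
        "haploid": sum(r.haploid for r in records),
        "mixoploid": sum(r.mixoploid for r in records),
        "diploid": sum(r.diploid for r in records),
    }
    acc = totals["acclimatized"]
    report = {
        "totals": totals,
        "per_record": [
            {
                "genotype": r.genotype,
                "protocol": r.protocol,
                "range_label": r.range_label,
                "response_pct": r.response_pct,
                "response_se": r.response_se,
                "response_type": r.response_type,
            }
            for r in records
        ],
        "acclimatization_pct": round(100.0 * acc / totals["embryos"], 1)
        if totals["embryos"]
        else 0.0,
        "ploidy_pct": {
            "haploid": round(100.0 * totals["haploid"] / acc, 1) if acc else 0.0,
            "mixoploid": round(100.0 * totals["mixoploid"] / acc, 1) if acc else 0.0,
            "diploid": round(100.0 * totals["diploid"] / acc, 1) if acc else 0.0,
        },
    }
    return report


def report_to_frame(records) -> pd.DataFrame:
    """Outcome table: one row per genotype with embryo/plant/ploidy counts."""
    rows = [
        {
            "Genotype": r.genotype,
            "Embryos (n)": r.embryos,
            "Acclimatized Plants (n)": r.acclimatized,
            "n": r.haploid,
            "n + 2n": r.mixoploid,
            "2n": r.diploid,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic family generator (testing without real genotypes)


def simulate_family(
    n_positions=532,
    n_bc=6,
    n_dh=10,
    bc_het_rate=0.5,
    dh_residual_het=0.01,
    missing_rate=0.01,
    donor_id="donor",
    seed=0,
) -> GenotypeMatrix:
    """Simulate a donor + backcross + DH family over donor-Het SNPs.

    The donor is heterozygous at every position (that is how the positions
    were selected); each backcross (BC) offspring inherits Het with
    probability ``bc_het_rate`` (one recombinant donor gamete against the
    recurrent parent); DH individuals are homozygous apart from a residual
    ``dh_residual_het`` mimicking somaclonal variation or paralog mapping.
    Calls go missing independently at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    samples = [donor_id] + [f"BC4_{i+1}" for i in range(n_bc)] + [
        f"DH_{i+1}" for i in range(n_dh)
    ]
    groups = {donor_id: "donor"}
    groups.update({f"BC4_{i+1}": "BC4" for i in range(n_bc)})
    groups.update({f"DH_{i+1}": "DH" for i in range(n_dh)})
    calls = np.empty((len(samples), n_positions), np.int8)
    calls[0] = HET
    for i in range(n_bc):
        het = rng.random(n_positions) < bc_het_rate
        calls[1 + i] = np.where(het, HET, HOM_REF)
    for i in range(n_dh):
        het = rng.random(n_positions) < dh_residual_het
        hom = np.where(rng.random(n_positions) < 0.5, HOM_REF, HOM_ALT)
        calls[1 + n_bc + i] = np.where(het, HET, hom)
    if missing_rate > 0:
        drop = rng.random(calls.shape) < missing_rate
        drop[0] = False  # keep the donor fully called: positions were chosen on it
        calls[drop] = MISSING
    return GenotypeMatrix(
        samples=samples,
        positions=[f"SNP_{j+1}" for j in range(n_positions)],
        calls=calls,
        groups=groups,
    )
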