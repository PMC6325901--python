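"""PLINK text genotype I/O and the shared in-memory data model.

Conventions used throughout the package:

* Coordinates are 1-based, inclusive, physical base pairs.  The length of
  any interval is ``end - start + 1``.
* Genotype calls are stored as ``int8`` codes: ``HOM_A = 0``, ``HET = 1``,
  ``HOM_B = 2``, ``MISSING = -1``.  ROH calling only needs to distinguish
  heterozygous from non-heterozygous calls, so the A/B labelling is
  arbitrary but stable: the first allele observed at a marker is A.
* Chromosome labels are strings; the canonical dog karyotype is autosomes
  "1".."38" plus "X", but smaller synthetic genomes may use any subset
  (pass ``allowed_chromosomes``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Genotype call codes.
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = -1

#: Canonical dog chromosome labels: 38 autosomes plus X.
DOG_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 39)) + ("X",)


def _chrom_sort_key(label: str) -> tuple[int, int]:
    """Numeric chromosomes in order, then X, then anything else."""
    if label.isdigit():
        return (0, int(label))
    if label == "X":
        return (1, 0)
    return (2, 0)


class PlinkFormatError(ValueError):
    """Raised for malformed .ped/.map or metadata input."""


@dataclass
class MarkerMap:
    """Ordered genomic marker coordinates, grouped by chromosome.

    ``table`` has columns ``chrom`` (str), ``marker_id`` (str), ``cm``
    (float, may be 0) and ``pos`` (int, 1-based bp), sorted by chromosome
    (numeric order, X last) and, within each chromosome, by position.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise PlinkFormatError(f"duplicate marker id {dup!r}")
        for chrom, grp in t.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise PlinkFormatError(
                    f"positions on chromosome {chrom} not strictly increasing"
                )
            if np.any(pos <= 0):
                raise PlinkFormatError(f"non-positive position on chromosome {chrom}")
        self.table = t

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str],
        marker_id: Sequence[str],
        pos: Sequence[int],
        cm: Sequence[float] | None = None,
        allowed_chromosomes: Iterable[str] | None = DOG_CHROMOSOMES,
    ) -> "MarkerMap":
        t = pd.DataFrame(
            {
                "chrom": [str(c) for c in chrom],
                "marker_id": [str(m) for m in marker_id],
                "cm": np.zeros(len(pos)) if cm is None else np.asarray(cm, float),
                "pos": np.asarray(pos, dtype=np.int64),
            }
        )
        if allowed_chromosomes is not None:
            bad = set(t["chrom"]) - set(allowed_chromosomes)
            if bad:
                raise PlinkFormatError(f"unknown chromosome label(s): {sorted(bad)}")
        order = sorted(
            range(len(t)),
            key=lambda i: (_chrom_sort_key(t["chrom"].iat[i]), t["pos"].iat[i]),
        )
        if order != list(range(len(t))):
            logger.info("marker map was unsorted; re-sorted by chromosome and position")
            t = t.iloc[order]
        return cls(t)

    # -- accessors ---------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in stored order."""
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def positions(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slice(chrom)
        return self.table["pos"].to_numpy()[sl]

    def chrom_span(self, chrom: str) -> int:
        """First-to-last marker span of a chromosome (bp, inclusive)."""
        pos = self.positions(chrom)
        if pos.size == 0:
            return 0
        return int(pos[-1] - pos[0] + 1)


@dataclass
class GenotypePanel:
    """Samples x markers diploid call matrix plus per-sample metadata.

    ``calls`` is ``int8`` of shape (n_samples, n_markers) using the module
    call codes.  ``metadata`` is indexed by sample id with columns ``breed``
    (str or None) and ``sex`` ("F", "M" or "U").  ``alleles`` holds the two
    allele symbols per marker for writing back to .ped.
    """

    markers: MarkerMap
    samples: list[str]
    calls: np.ndarray
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    alleles: list[tuple[str, str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), self.markers.n_markers):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {self.markers.n_markers} markers"
            )
        if len(set(self.samples)) != len(self.samples):
            raise PlinkFormatError("duplicate sample id in panel")
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                {"breed": [None] * len(self.samples), "sex": ["U"] * len(self.samples)},
                index=pd.Index(self.samples, name="sample"),
            )
        if self.alleles is None:
            self.alleles = [("A", "B")] * self.markers.n_markers

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[self.sample_index(sample)]

    def sex(self, sample: str) -> str:
        return str(self.metadata.loc[sample, "sex"])

    def breed(self, sample: str) -> str | None:
        b = self.metadata.loc[sample, "breed"]
        return None if pd.isna(b) else str(b)

    def subset_samples(self, keep: Sequence[str]) -> "GenotypePanel":
        idx = [self.sample_index(s) for s in keep]
        return GenotypePanel(
            markers=self.markers,
            samples=list(keep),
            calls=self.calls[idx],
            metadata=self.metadata.loc[list(keep)].copy(),
            alleles=self.alleles,
        )

    def subset_markers(self, keep_ids: Sequence[str]) -> "GenotypePanel":
        keep = set(keep_ids)
        mask = self.markers.table["marker_id"].isin(keep).to_numpy()
        mm = MarkerMap(self.markers.table.loc[mask])
        return GenotypePanel(
            markers=mm,
            samples=list(self.samples),
            calls=self.calls[:, mask],
            metadata=self.metadata.copy(),
            alleles=[a for a, m in zip(self.alleles, mask) if m],
        )

    def x_het_violations(
        self, pseudoautosomal: tuple[int, int] | None = None
    ) -> pd.DataFrame:
        """Flag heterozygous chrX calls in male samples.

        Males are hemizygous on X outside the pseudoautosomal region, so a
        HET call there is a genotyping artifact.  Violations are reported,
        never silently altered.
        """
        sl = self.markers.chrom_slice("X")
        rows = []
        if sl.stop > sl.start:
            pos = self.markers.table["pos"].to_numpy()[sl]
            ids = self.markers.table["marker_id"].to_numpy()[sl]
            in_par = (
                (pos >= pseudoautosomal[0]) & (pos <= pseudoautosomal[1])
                if pseudoautosomal is not None
                else np.zeros(pos.size, dtype=bool)
            )
            for i, s in enumerate(self.samples):
                if self.metadata.loc[s, "sex"] != "M":
                    continue
                het = (self.calls[i, sl] == HET) & ~in_par
                for j in np.flatnonzero(het):
                    rows.append({"sample": s, "marker_id": ids[j], "pos": int(pos[j])})
        return pd.DataFrame(rows, columns=["sample", "marker_id", "pos"])


@dataclass
class DiseaseLocusTable:
    """Known recessive disease loci plus observed at-risk (homozygous) records.

    ``loci``: columns ``locus_id``, ``chrom``, ``pos``, ``risk_allele``.
    ``records``: columns ``sample``, ``locus_id`` — one row per at-risk
    genotype (a sample homozygous for the risk allele at that locus).
    """

    loci: pd.DataFrame
    records: pd.DataFrame

    def flag_off_grid(self, markers: MarkerMap) -> pd.Series:
        """True for loci outside the marker span of their chromosome."""
        flags = {}
        for _, row in self.loci.iterrows():
            pos = markers.positions(str(row["chrom"]))
            off = pos.size == 0 or not (pos[0] <= row["pos"] <= pos[-1])
            flags[row["locus_id"]] = bool(off)
        return pd.Series(flags, name="off_grid")


# ---------------------------------------------------------------------------
# PLINK text readers / writers
# ---------------------------------------------------------------------------

_SEX_FROM_PED = {"1": "M", "2": "F"}
_SEX_TO_PED = {"M": "1", "F": "2", "U": "0"}


def read_map(map_path: str | Path, allowed_chromosomes=DOG_CHROMOSOMES) -> MarkerMap:
    """Read a 4-column PLINK .map file (chrom, id, cM, bp)."""
    chroms, ids, cms, poss = [], [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise PlinkFormatError(
                    f"{map_path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            chroms.append(fields[0])
            ids.append(fields[1])
            cms.append(float(fields[2]))
            poss.append(int(fields[3]))
    return MarkerMap.from_arrays(
        chroms, ids, poss, cms, allowed_chromosomes=allowed_chromosomes
    )


def read_plink(
    ped_path: str | Path,
    map_path: str | Path,
    allowed_chromosomes=DOG_CHROMOSOMES,
) -> GenotypePanel:
    """Read a PLINK 1.x text fileset into a :class:`GenotypePanel`.

    Alleles are normalized per marker so that HOM_A/HOM_B are consistent
    across samples: the first non-missing allele observed is A.  "0 0"
    (and half-missing calls) become MISSING.  Markers follow the .map order
    after a within-chromosome position sort.
    """
    mm = read_map(map_path, allowed_chromosomes=allowed_chromosomes)
    n_markers = mm.n_markers
    # read_map may have re-sorted; recover the permutation from original file
    # order to the stored order so .ped columns land on the right marker.
    raw_ids = []
    with open(map_path) as fh:
        for line in fh:
            if line.strip():
                raw_ids.append(line.split()[1])
    stored_order = {m: i for i, m in enumerate(mm.table["marker_id"])}
    perm = np.array([stored_order[m] for m in raw_ids], dtype=np.int64)

    samples: list[str] = []
    sexes: list[str] = []
    call_rows: list[np.ndarray] = []
    allele_a: list[str | None] = [None] * n_markers
    allele_b: list[str | None] = [None] * n_markers

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_markers:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields "
                    f"(6 + 2x{n_markers} markers), got {len(fields)}"
                )
            iid = fields[1]
            if iid in samples:
                raise PlinkFormatError(f"{ped_path}:{lineno}: duplicate sample id {iid!r}")
            samples.append(iid)
            sexes.append(_SEX_FROM_PED.get(fields[4], "U"))
            row = np.full(n_markers, MISSING, dtype=np.int8)
            for k in range(n_markers):
                a1, a2 = fields[6 + 2 * k], fields[7 + 2 * k]
                if a1 == "0" or a2 == "0":
                    continue  # fully or half missing -> MISSING
                j = int(perm[k])
                for al in (a1, a2):
                    if allele_a[j] is None:
                        allele_a[j] = al
                    elif al != allele_a[j] and allele_b[j] is None:
                        allele_b[j] = al
                    elif al not in (allele_a[j], allele_b[j]):
                        raise PlinkFormatError(
                            f"{ped_path}:{lineno}: marker {mm.table['marker_id'].iat[j]!r}"
                            f" has more than two alleles"
                        )
                na = (a1 == allele_b[j]) + (a2 == allele_b[j])
                row[j] = (HOM_A, HET, HOM_B)[na]
            call_rows.append(row)

    calls = (
        np.vstack(call_rows) if call_rows else np.empty((0, n_markers), dtype=np.int8)
    )
    metadata = pd.DataFrame(
        {"breed": [None] * len(samples), "sex": sexes},
        index=pd.Index(samples, name="sample"),
    )
    alleles = [
        (a if a is not None else "A", b if b is not None else "B")
        for a, b in zip(allele_a, allele_b)
    ]
    return GenotypePanel(mm, samples, calls, metadata, alleles)


def write_plink(panel: GenotypePanel, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a panel as a whitespace-delimited PLINK 1.x text fileset."""
    t = panel.markers.table
    with open(map_path, "w") as fh:
        for chrom, mid, cm, pos in zip(t["chrom"], t["marker_id"], t["cm"], t["pos"]):
            fh.write(f"{chrom}\t{mid}\t{cm:g}\t{pos}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(panel.samples):
            sex = _SEX_TO_PED.get(str(panel.metadata.loc[s, "sex"]), "0")
            parts = [s, s, "0", "0", sex, "-9"]
            row = panel.calls[i]
            for j in range(panel.markers.n_markers):
                a, b = panel.alleles[j]
                c = row[j]
                if c == HOM_A:
                    parts += [a, a]
                elif c == HET:
                    parts += [a, b]
                elif c == HOM_B:
                    parts += [b, b]
                else:
                    parts += ["0", "0"]
            fh.write(" ".join(parts) + "\n")


def read_disease_table(path: str | Path) -> DiseaseLocusTable:
    """Read a disease-locus / at-risk-record table.

    Expected delimited text (tab or comma) with header columns
    ``locus_id, chrom, pos, risk_allele, sample``.  Rows with an empty or
    "." sample declare a locus without an at-risk record; rows with a
    sample id are at-risk records.  A record row must either carry the
    locus coordinates or reference a locus declared elsewhere in the file.
    Duplicate (sample, locus) rows are collapsed with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    required = {"locus_id", "chrom", "pos", "risk_allele", "sample"}
    missing = required - set(df.columns)
    if missing:
        raise PlinkFormatError(f"{path}: missing column(s) {sorted(missing)}")

    loci: dict[str, dict] = {}
    for _, row in df.iterrows():
        lid = row["locus_id"]
        if row["chrom"] not in ("", ".") and row["pos"] not in ("", "."):
            entry = {
                "locus_id": lid,
                "chrom": str(row["chrom"]),
                "pos": int(row["pos"]),
                "risk_allele": row["risk_allele"] or "B",
            }
            if lid in loci and loci[lid] != entry:
                raise PlinkFormatError(f"{path}: conflicting definitions for locus {lid!r}")
            loci[lid] = entry

    records = []
    for _, row in df.iterrows():
        s = row["sample"]
        if s in ("", "."):
            continue
        if row["locus_id"] not in loci:
            raise PlinkFormatError(
                f"{path}: at-risk record for unknown locus {row['locus_id']!r}"
            )
        records.append({"sample": s, "locus_id": row["locus_id"]})

    rec_df = pd.DataFrame(records, columns=["sample", "locus_id"])
    n_before = len(rec_df)
    rec_df = rec_df.drop_duplicates().reset_index(drop=True)
    if len(rec_df) < n_before:
        logger.warning(
            "%s: collapsed %d duplicate (sample, locus) rows", path, n_before - len(rec_df)
        )
    loci_df = pd.DataFrame(
        list(loci.values()), columns=["locus_id", "chrom", "pos", "risk_allele"]
    )
    return DiseaseLocusTable(loci_df, rec_df)
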