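"""Genotype-matrix and genetic-map containers and their text formats.

Genotypes are biallelic SNP calls coded as allele counts 0/1/2 with an
explicit missing sentinel (``MISSING`` = -1 internally, ``NA`` on disk).
For polyploid VCF genotypes a pseudo-diploid collapse is applied: every
heterozygous dosage class becomes code 1, so the matrix is always in the
0/1/2 alphabet regardless of ploidy.

Formats
-------
* genotype matrix: delimited text (TSV, or CSV for ``.csv`` paths), header
  row of marker ids, first column sample ids, cells in {0,1,2,NA}.
* VCF 4.x (GT subfield only) through cyvcf2; multi-allelic records are
  skipped and counted, not split.
* genetic map and extended map: TSV/CSV with columns ``marker_id``,
  ``linkage_group``, ``position_cM`` (extra columns are ignored on read);
  positions are serialized with 6 decimals so round-trips are bit-stable.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: In-memory sentinel for a missing genotype call.
MISSING: int = -1

#: Missing-value spellings accepted in text matrices.
MISSING_TOKENS = frozenset({"NA", "N", "-9", "", "nan", "NaN"})

_POSITION_FMT = "%.6f"


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _atomic_write_text(path: str, text: str) -> None:
    """Write text to *path* via a temp file so failures never leave partial output."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".lodemap-tmp-")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


class GenotypeMatrix:
    """Samples x markers matrix of 0/1/2 calls with missing values.

    Parameters
    ----------
    sample_ids, marker_ids
        Unique identifiers for the rows and columns of ``calls``.
    calls
        Integer array of shape ``(n_samples, n_markers)`` with values in
        {0, 1, 2, MISSING}.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        marker_ids: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        sample_ids = [str(s) for s in sample_ids]
        marker_ids = [str(m) for m in marker_ids]
        calls = np.asarray(calls)
        if calls.ndim != 2 or calls.shape != (len(sample_ids), len(marker_ids)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(sample_ids)} samples x {len(marker_ids)} markers"
            )
        for label, ids in (("sample", sample_ids), ("marker", marker_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {label} id(s): {dupes[:5]}")
        calls = calls.astype(np.int8, copy=False)
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call {calls[r, c]} at sample {sample_ids[r]!r}, "
                f"marker {marker_ids[c]!r}"
            )
        self.sample_ids: list[str] = sample_ids
        self.marker_ids: list[str] = marker_ids
        self.calls: np.ndarray = calls
        self._marker_index = {m: j for j, m in enumerate(marker_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._marker_index

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def column(self, marker_id: str) -> np.ndarray:
        """Call vector for one marker (missing as MISSING)."""
        return self.calls[:, self.marker_index(marker_id)]

    def columns(self, marker_ids: Iterable[str]) -> np.ndarray:
        idx = [self.marker_index(m) for m in marker_ids]
        return self.calls[:, idx]

    def take_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(marker_ids)
        return GenotypeMatrix(self.sample_ids, ids, self.columns(ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.sample_ids, columns=self.marker_ids, copy=True
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers)"


class GeneticMap:
    """Marker -> (linkage group, cM position) lookup.

    Positions must be finite and non-negative, markers unique.  Unless
    ``require_linked=False`` (used for held-out truth sets) at least one
    linkage group must carry two or more markers, since LD-weighted
    placement is vacuous otherwise.
    """

    def __init__(
        self,
        entries: Mapping[str, tuple[str, float]] | Iterable[tuple[str, str, float]],
        require_linked: bool = True,
    ) -> None:
        if isinstance(entries, Mapping):
            triples = [(m, lg, pos) for m, (lg, pos) in entries.items()]
        else:
            triples = [(m, lg, pos) for m, lg, pos in entries]
        if not triples:
            raise ValidationError("genetic map is empty")
        self._lg: dict[str, str] = {}
        self._pos: dict[str, float] = {}
        for m, lg, pos in triples:
            m = str(m)
            if m in self._lg:
                raise ValidationError(f"duplicate marker id in map: {m!r}")
            pos = float(pos)
            if not np.isfinite(pos) or pos < 0:
                raise ValidationError(f"invalid position {pos} for marker {m!r}")
            self._lg[m] = str(lg)
            self._pos[m] = pos
        if require_linked:
            sizes: dict[str, int] = {}
            for lg in self._lg.values():
                sizes[lg] = sizes.get(lg, 0) + 1
            if max(sizes.values()) < 2:
                raise ValidationError(
                    "no linkage group holds >= 2 markers; weighted placement is vacuous"
                )

    # -- lookups -------------------------------------------------------------
    @property
    def markers(self) -> list[str]:
        return list(self._lg)

    def __len__(self) -> int:
        return len(self._lg)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._lg

    def linkage_group(self, marker_id: str) -> str:
        return self._lg[marker_id]

    def position(self, marker_id: str) -> float:
        return self._pos[marker_id]

    def entry(self, marker_id: str) -> tuple[str, float]:
        return self._lg[marker_id], self._pos[marker_id]

    @property
    def linkage_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for lg in self._lg.values():
            seen.setdefault(lg)
        return list(seen)

    def groups(self) -> dict[str, list[str]]:
        """Markers per linkage group, preserving map order."""
        out: dict[str, list[str]] = {}
        for m, lg in self._lg.items():
            out.setdefault(lg, []).append(m)
        return out

    def drop(self, marker_ids: Iterable[str], require_linked: bool = True) -> "GeneticMap":
        gone = set(marker_ids)
        return GeneticMap(
            [(m, lg, self._pos[m]) for m, lg in self._lg.items() if m not in gone],
            require_linked=require_linked,
        )

    def subset(self, marker_ids: Iterable[str], require_linked: bool = False) -> "GeneticMap":
        return GeneticMap(
            [(m, self._lg[m], self._pos[m]) for m in marker_ids],
            require_linked=require_linked,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": list(self._lg),
                "linkage_group": list(self._lg.values()),
                "position_cM": [self._pos[m] for m in self._lg],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneticMap({len(self)} markers, {len(self.linkage_groups)} linkage groups)"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path: str, dialect: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a delimited text file or a VCF.

    ``dialect`` is ``"matrix"`` or ``"vcf"``; when ``None`` it is inferred
    from the file extension (``.vcf``/``.vcf.gz`` -> vcf, else matrix).
    """
    if dialect is None:
        dialect = "vcf" if str(path).lower().endswith((".vcf", ".vcf.gz")) else "matrix"
    if dialect == "matrix":
        return _read_matrix(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_matrix(path: str) -> GenotypeMatrix:
    # pandas mangles duplicate header names; check the raw header first
    sep = _sep_for(path)
    with open(path) as handle:
        for line in handle:
            if line.strip() and not line.startswith("#"):
                header = [c.strip() for c in line.rstrip("\n").split(sep)][1:]
                break
        else:
            raise ParseError(f"genotype matrix {path} is empty")
    if len(set(header)) != len(header):
        dupes = sorted({m for m in header if header.count(m) > 1})
        raise ValidationError(f"duplicate marker id(s): {dupes[:5]}")
    try:
        df = pd.read_csv(
            path,
            sep=_sep_for(path),
            index_col=0,
            dtype=str,
            comment="#",
            keep_default_na=False,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed tables
        raise ParseError(f"cannot read genotype matrix {path}: {exc}") from exc
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample id(s): {dupes[:5]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate marker id(s): {dupes[:5]}")

    raw = df.to_numpy(dtype=object)
    calls = np.empty(raw.shape, dtype=np.int8)
    lookup = {"0": 0, "1": 1, "2": 2}
    for token in MISSING_TOKENS:
        lookup[token] = MISSING
    # token-wise mapping with a precise error location for anything unknown
    for token in pd.unique(raw.ravel()):
        key = str(token).strip()
        if key not in lookup:
            r, c = np.argwhere(raw == token)[0]
            raise ParseError(
                f"invalid genotype {token!r} at row {df.index[r]!r} "
                f"(sample), column {df.columns[c]!r} (marker) in {path}"
            )
        calls[raw == token] = lookup[key]
    return GenotypeMatrix(df.index.tolist(), df.columns.tolist(), calls)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: htslib import is slow

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        vid = variant.ID
        if vid is None or vid == ".":
            vid = f"{variant.CHROM}:{variant.POS}"
        col = np.empty(len(samples), dtype=np.int8)
        for i, geno in enumerate(variant.genotypes):
            alleles = geno[:-1]  # last entry is the phased flag
            if len(alleles) == 0 or any(a < 0 for a in alleles):
                col[i] = MISSING
            elif all(a == 0 for a in alleles):
                col[i] = 0
            elif all(a > 0 for a in alleles):
                col[i] = 2
            else:  # pseudo-diploid collapse: any mixed dosage is one het class
                col[i] = 1
        marker_ids.append(vid)
        columns.append(col)
    if n_skipped:
        logger.warning("skipped %d non-biallelic VCF record(s) in %s", n_skipped, path)
    if not columns:
        raise ParseError(f"no usable biallelic records in {path}")
    g = GenotypeMatrix(samples, marker_ids, np.column_stack(columns))
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


def read_genetic_map(path: str) -> GeneticMap:
    """Read a genetic map table (marker_id, linkage_group, position_cM)."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot read genetic map {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"genetic map {path} is empty")
    required = ["marker_id", "linkage_group", "position_cM"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"genetic map {path} lacks column(s) {missing_cols}")
    triples = []
    for row in df.itertuples(index=True):
        try:
            pos = float(row.position_cM)
        except (TypeError, ValueError):
            raise ParseError(
                f"non-numeric position {row.position_cM!r} at row {row.Index} "
                f"(marker {row.marker_id!r}) in {path}"
            ) from None
        if not np.isfinite(pos) or pos < 0:
            raise ParseError(
                f"invalid position {pos} at row {row.Index} "
                f"(marker {row.marker_id!r}) in {path}"
            )
        triples.append((row.marker_id, row.linkage_group, pos))
    return GeneticMap(triples)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path: str) -> None:
    """Write a genotype matrix in the delimited-text dialect (NA = missing)."""
    df = g.to_dataframe().astype(object)
    df[df == MISSING] = "NA"
    _atomic_write_text(path, df.to_csv(sep=_sep_for(path), index_label="sample_id"))


def write_genetic_map(gmap: GeneticMap, path: str, header_lines: Sequence[str] = ()) -> None:
    df = gmap.to_dataframe()
    df["position_cM"] = [_POSITION_FMT % p for p in df["position_cM"]]
    text = "".join(f"# {line}\n" for line in header_lines)
    text += df.to_csv(sep=_sep_for(path), index=False)
    _atomic_write_text(path, text)


def write_extended_map(gmap: GeneticMap, placements, path: str,
                       header_lines: Sequence[str] = ()) -> None:
    """Write anchors plus LD-placed markers as one extended-map table.

    Columns: marker_id, linkage_group, position_cM, source (anchor |
    ld_placed), top_r2, n_anchors.  Anchors come first, each block sorted
    by linkage group then position.  The file round-trips through
    :func:`read_genetic_map`, which ignores the extra columns.
    """
    placed = [p for p in placements if getattr(p, "status", "placed") == "placed"]
    overlap = [p.marker_id for p in placed if p.marker_id in gmap]
    if overlap:
        raise ValidationError(
            f"placed marker id(s) already on the anchor map: {overlap[:5]}"
        )
    anchors = gmap.to_dataframe()
    anchors["source"] = "anchor"
    anchors["top_r2"] = ""
    anchors["n_anchors"] = ""
    anchors = anchors.sort_values(
        ["linkage_group", "position_cM"], kind="stable"
    )
    rows = [
        {
            "marker_id": p.marker_id,
            "linkage_group": p.linkage_group,
            "position_cM": p.position,
            "source": "ld_placed",
            "top_r2": "%.6g" % p.top_r2,
            "n_anchors": p.n_anchors_used,
        }
        for p in placed
    ]
    if rows:
        extra = pd.DataFrame(rows).sort_values(
            ["linkage_group", "position_cM"], kind="stable"
        )
        out = pd.concat([anchors, extra], ignore_index=True)
    else:
        out = anchors
    out["position_cM"] = [_POSITION_FMT % p for p in out["position_cM"].astype(float)]
    text = "".join(f"# {line}\n" for line in header_lines)
    text += out.to_csv(sep=_sep_for(path), index=False)
    _atomic_write_text(path, text)


def write_placement_report(placements, path: str, header_lines: Sequence[str] = ()) -> None:
    """One row per candidate with every placement field (TSV/CSV by extension)."""
    rows = []
    for p in placements:
        rows.append(
            {
                "marker_id": p.marker_id,
                "status": p.status,
                "linkage_group": "" if p.linkage_group is None else p.linkage_group,
                "position_cM": "" if p.position is None else _POSITION_FMT % p.position,
                "top_r2": "" if p.top_r2 is None else "%.6g" % p.top_r2,
                "second_r2": "" if p.second_r2 is None else "%.6g" % p.second_r2,
                "n_anchors_used": p.n_anchors_used,
                "reason": "" if p.reason is None else p.reason,
                "detail": "" if p.detail is None else p.detail,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "marker_id", "status", "linkage_group", "position_cM",
            "top_r2", "second_r2", "n_anchors_used", "reason", "detail",
        ],
    )
    text = "".join(f"# {line}\n" for line in header_lines)
    text += df.to_csv(sep=_sep_for(path), index=False)
    _atomic_write_text(path, text)
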