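"""Probe annotation: gene context, CpG-island relation, direction counts.

Positions are 1-based; CpG-island intervals are half-open ``[start,
end)`` on the same 1-based coordinates. A probe is classified as
*island* when its position falls inside an interval, *shore* within
``shore_width`` bp of an island edge, *shelf* within a further
``shelf_width`` bp, and *open_sea* otherwise (2 kb defaults, the usual
convention). Every probe maps to exactly one category.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SHORE_WIDTH = 2000
SHELF_WIDTH = 2000


class AnnotationError(ValueError):
    pass


class ProbeAnnotation:
    """Per-probe genomic context plus per-chromosome island intervals.

    ``probes``: DataFrame indexed by probe_id with columns chrom, pos
    (1-based) and gene (';'-joined symbols, possibly empty).
    ``islands``: mapping chrom -> (n, 2) array of half-open intervals,
    sorted and non-overlapping.
    """

    def __init__(self, probes: pd.DataFrame, islands: dict[str, np.ndarray] | None = None):
        self.probes = probes
        self.islands = {}
        for chrom, iv in (islands or {}).items():
            arr = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            arr = arr[np.argsort(arr[:, 0])]
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise AnnotationError(f"malformed island interval on {chrom}")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise AnnotationError(f"overlapping island intervals on {chrom}")
            self.islands[chrom] = arr

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Flat TSV layout: probe_id, chrom, pos, gene, island_* columns.

        The island columns carry the nearest island interval when the
        probe lies within shelf distance of one, else blanks.
        """
        df = self.probes.copy()
        rel, ichrom, istart, iend = [], [], [], []
        for pid, row in df.iterrows():
            r, iv = self._classify_one(row["chrom"], int(row["pos"]))
            rel.append(r)
            if iv is None:
                ichrom.append("")
                istart.append("")
                iend.append("")
            else:
                ichrom.append(row["chrom"])
                istart.append(int(iv[0]))
                iend.append(int(iv[1]))
        df["island_relation"] = rel
        df["island_chrom"] = ichrom
        df["island_start"] = istart
        df["island_end"] = iend
        df.index.name = "probe_id"
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "ProbeAnnotation":
        df = pd.read_csv(path, sep="\t", index_col="probe_id",
                         dtype={"island_chrom": str}, keep_default_na=False,
                         na_values=[""])
        islands: dict[str, list] = {}
        has = df["island_chrom"].notna() if "island_chrom" in df else pd.Series(False, index=df.index)
        for _, row in df[has].iterrows():
            islands.setdefault(str(row["island_chrom"]), []).append(
                (int(row["island_start"]), int(row["island_end"]))
            )
        islands_u = {c: np.unique(np.asarray(v, dtype=np.int64), axis=0) for c, v in islands.items()}
        probes = df[["chrom", "pos", "gene"]].copy()
        probes["chrom"] = probes["chrom"].astype(str)
        probes["gene"] = probes["gene"].fillna("")
        return cls(probes, islands_u)

    @classmethod
    def islands_from_bed(cls, probes: pd.DataFrame, bed_path) -> "ProbeAnnotation":
        """Build with islands from a BED file (0-based half-open on read,
        converted to the package's 1-based half-open convention)."""
        islands: dict[str, list] = {}
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split()[:3]
                islands.setdefault(chrom, []).append((int(start) + 1, int(end) + 1))
        return cls(probes, {c: np.asarray(v) for c, v in islands.items()})

    # -- classification ------------------------------------------------
    def _classify_one(self, chrom: str, pos: int,
                      shore_width: int = SHORE_WIDTH, shelf_width: int = SHELF_WIDTH):
        iv = self.islands.get(str(chrom))
        if iv is None or len(iv) == 0:
            return "open_sea", None
        # distance to each island's closed hull [start, end-1]
        d = np.where(
            pos < iv[:, 0], iv[:, 0] - pos,
            np.where(pos >= iv[:, 1], pos - iv[:, 1] + 1, 0),
        )
        j = int(np.argmin(d))
        dist = int(d[j])
        if dist == 0:
            return "island", iv[j]
        if dist <= shore_width:
            return "shore", iv[j]
        if dist <= shore_width + shelf_width:
            return "shelf", iv[j]
        return "open_sea", None

    def classify(self, probe_ids=None, shore_width: int = SHORE_WIDTH,
                 shelf_width: int = SHELF_WIDTH) -> pd.Series:
        """Island/shore/shelf/open-sea category per probe."""
        ids = self.probes.index if probe_ids is None else probe_ids
        missing = [p for p in ids if p not in self.probes.index]
        if missing:
            raise AnnotationError(f"unknown probe ids: {missing[:5]}")
        out = {}
        for pid in ids:
            row = self.probes.loc[pid]
            out[pid] = self._classify_one(row["chrom"], int(row["pos"]),
                                          shore_width, shelf_width)[0]
        return pd.Series(out, name="island_relation")


def classify_island_relation(pos: int, islands, shore_width: int = SHORE_WIDTH,
                             shelf_width: int = SHELF_WIDTH) -> str:
    """Classify a single 1-based position against sorted half-open islands."""
    ann = ProbeAnnotation(
        pd.DataFrame({"chrom": ["x"], "pos": [pos], "gene": [""]}, index=["q"]),
        {"x": np.asarray(islands, dtype=np.int64).reshape(-1, 2)} if len(islands) else {},
    )
    return ann._classify_one("x", pos, shore_width, shelf_width)[0]


def direction_summary(coefficients) -> dict[str, int]:
    """Count hypo- (coef < 0), hyper- (coef > 0) and zero-coefficient sites."""
    c = np.asarray(coefficients, dtype=float)
    return {
        "hypo": int((c < 0).sum()),
        "hyper": int((c > 0).sum()),
        "zero": int((c == 0).sum()),
    }


def map_sites_to_genes(probe_ids, annotation: ProbeAnnotation) -> list[str]:
    """Unique gene symbols for a probe set.

    ';'-joined multi-gene entries are split; empties dropped; order is
    stable by first occurrence.
    """
    probes = annotation.probes if isinstance(annotation, ProbeAnnotation) else annotation
    missing = [p for p in probe_ids if p not in probes.index]
    if missing:
        raise AnnotationError(f"unknown probe ids: {missing[:5]}")
    seen: dict[str, None] = {}
    for pid in probe_ids:
        field = probes.loc[pid, "gene"]
        if pd.isna(field) or field == "":
            continue
        for g in str(field).split(";"):
            g = g.strip()
            if g:
                seen.setdefault(g)
    return list(seen)
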