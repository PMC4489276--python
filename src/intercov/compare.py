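"""Ranking, inter/intra classification, links-needed thresholds, method
overlap and score-density summaries for pairwise covariation scores.

The central question this layer answers mirrors how a paired-alignment
analysis is actually read: "how deep into the overall ranking must I go to
see n interprotein links?", and "which top pairs do several methods agree
on?". Ties are broken deterministically by (score desc, i asc, j asc).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

INTER = "inter"


@dataclass
class ScoreTable:
    """Symmetric pairwise score matrix for one method over a paired MSA."""

    method: str
    scores: np.ndarray                       # (L, L) symmetric
    segments: list[tuple[str, int, int]]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        L = self.scores.shape[0]
        if self.scores.shape != (L, L):
            raise ValueError("scores must be a square matrix")
        end = self.segments[-1][2]
        if end != L:
            raise ValueError(f"segments cover {end} columns but scores have "
                             f"{L}")

    @property
    def L(self) -> int:
        return self.scores.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.L * (self.L - 1) // 2


def segment_labels(segments, L) -> np.ndarray:
    """Per-column protein label; errors on columns outside all segments."""
    labels = np.empty(L, dtype=object)
    for label, start, end in segments:
        if start < 0 or end > L:
            raise ValueError(f"segment {label!r} outside [0, {L})")
        labels[start:end] = label
    if any(l is None for l in labels):
        raise ValueError("position outside all segments")
    return labels


def classify_pairs(segments, L) -> np.ndarray:
    """(L, L) array of pair classes: 'inter' or 'intra:<label>'."""
    labels = segment_labels(segments, L)
    classes = np.empty((L, L), dtype=object)
    for i in range(L):
        same = labels == labels[i]
        classes[i] = np.where(same, "intra:" + labels[i], INTER)
    return classes


def _class_matches(cls: str, target: str) -> bool:
    if target == "both":
        return True
    if target == "intra":
        return cls.startswith("intra")
    if target == INTER:
        return cls == INTER
    return cls == target     # e.g. a specific 'intra:A'


def rank_pairs(table: ScoreTable) -> pd.DataFrame:
    """All unordered pairs ranked by descending score.

    Returns a DataFrame with columns (rank, i, j, score, cls); ties are
    broken by smaller i then smaller j. NaN scores are rejected.
    """
    L = table.L
    iu, ju = np.triu_indices(L, k=1)
    scores = table.scores[iu, ju]
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    order = np.lexsort((ju, iu, -scores))
    classes = classify_pairs(table.segments, L)
    df = pd.DataFrame({
        "rank": np.arange(1, iu.size + 1),
        "i": iu[order],
        "j": ju[order],
        "score": scores[order],
        "cls": classes[iu[order], ju[order]],
    })
    return df


def links_needed(ranked: pd.DataFrame, target_class: str, n: int) -> int:
    """Smallest k such that the top-k ranked pairs contain >= n pairs of
    ``target_class`` ('inter', 'intra', 'both' or a specific 'intra:X')."""
    if n < 1:
        raise ValueError("n must be >= 1")
    matches = ranked["cls"].map(lambda c: _class_matches(c, target_class))
    cum = np.cumsum(matches.to_numpy())
    total = int(cum[-1]) if cum.size else 0
    if total < n:
        raise ValueError(f"only {total} pairs of class {target_class!r} "
                         f"available, {n} requested")
    return int(np.searchsorted(cum, n) + 1)


def top_class_pairs(ranked: pd.DataFrame, target_class: str, n: int,
                    mode: str = "restricted") -> pd.DataFrame:
    """A method's top set for an overlap query.

    mode='restricted' (default): the first n ranked pairs of the target
    class — i.e. the class-restricted content of the top links_needed(n)
    overall ranks. mode='overall': the top-n overall pairs, then filtered
    to the target class.
    """
    if mode == "restricted":
        k = links_needed(ranked, target_class, n)
        top = ranked.iloc[:k]
        mask = top["cls"].map(lambda c: _class_matches(c, target_class))
        return top[mask]
    if mode == "overall":
        top = ranked.iloc[:n]
        mask = top["cls"].map(lambda c: _class_matches(c, target_class))
        return top[mask]
    raise ValueError(f"unknown overlap mode {mode!r}")


def top_overlap(ranked_tables: dict[str, pd.DataFrame], target_class: str,
                n: int, mode: str = "restricted") -> dict:
    """Overlap of the top sets of 2-4 methods.

    Returns the intersection pairs, and for the union of all top sets each
    method's rank of each pair (None when the pair is outside that
    method's ranking of the class)."""
    if not 2 <= len(ranked_tables) <= 4:
        raise ValueError("overlap requires between 2 and 4 methods")
    sizes = {len(df) for df in ranked_tables.values()}
    if len(sizes) != 1:
        raise ValueError("mismatched L: rankings have different pair counts")
    tops = {m: top_class_pairs(df, target_class, n, mode)
            for m, df in ranked_tables.items()}
    sets = {m: set(zip(df["i"], df["j"])) for m, df in tops.items()}
    inter = set.intersection(*sets.values())
    union = set.union(*sets.values())
    rank_lookup = {
        m: {(r.i, r.j): int(r.rank) for r in df.itertuples(index=False)}
        for m, df in ranked_tables.items()
    }
    report = []
    for (i, j) in sorted(union):
        report.append({
            "i": int(i), "j": int(j),
            "in_overlap": (i, j) in inter,
            "ranks": {m: rank_lookup[m].get((i, j)) for m in ranked_tables},
        })
    return {"target_class": target_class, "n": n, "mode": mode,
            "overlap": sorted(inter), "union_report": report}


def density_summary(table: ScoreTable, n_bins: int = 50) -> dict:
    """Count/mean/sd/quantiles and binned densities of the scores, split
    into inter, intra and inter+intra pair classes."""
    L = table.L
    iu, ju = np.triu_indices(L, k=1)
    scores = table.scores[iu, ju]
    classes = classify_pairs(table.segments, L)[iu, ju]
    is_inter = np.array([c == INTER for c in classes])
    out = {"method": table.method, "classes": {}}
    for name, mask in [("inter", is_inter), ("intra", ~is_inter),
                       ("inter+intra", np.ones_like(is_inter))]:
        vals = scores[mask]
        entry = {"count": int(vals.size)}
        if vals.size:
            qs = [1, 5, 25, 50, 75, 95, 99]
            entry.update({
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "quantiles": {str(p): float(np.percentile(vals, p))
                              for p in qs},
            })
            counts, edges = np.histogram(vals, bins=n_bins)
            entry["histogram"] = {"counts": counts.tolist(),
                                  "bin_edges": edges.tolist()}
        out["classes"][name] = entry
    return out


# ---------------------------------------------------------------------------
# score-table I/O


def export_scores(table: ScoreTable, path, reference: str | None = None,
                  extra: dict[str, np.ndarray] | None = None) -> None:
    """Write the per-pair score TSV.

    Columns: pos_i, pos_j (1-based reference positions), res_i, res_j,
    protein_i, protein_j, <method score>, any extra score matrices, class.
    """
    L = table.L
    labels = segment_labels(table.segments, L)
    classes = classify_pairs(table.segments, L)
    iu, ju = np.triu_indices(L, k=1)
    cols = {
        "pos_i": iu + 1,
        "pos_j": ju + 1,
    }
    if reference is not None:
        if len(reference) != L:
            raise ValueError("reference length does not match score matrix")
        cols["res_i"] = [reference[i] for i in iu]
        cols["res_j"] = [reference[j] for j in ju]
    cols["protein_i"] = labels[iu]
    cols["protein_j"] = labels[ju]
    cols[table.method] = table.scores[iu, ju]
    for name, mat in (extra or {}).items():
        cols[name] = np.asarray(mat)[iu, ju]
    cols["class"] = classes[iu, ju]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format="%.8g")


def import_external_scores(path, segments, L, method: str | None = None,
                           sparse: bool = False) -> ScoreTable:
    """Read an externally computed score file into a :class:`ScoreTable`.

    The file is a TSV of (i, j, score) with 1-based positions; a header
    line and ``# method: NAME`` comment are both honoured. The listing must
    cover every unordered pair unless ``sparse`` is set, in which case
    missing pairs get a sentinel that ranks last (-inf).
    """
    meta_method = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "method:" in line:
                meta_method = line.split("method:")[1].strip()
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 3:
        raise ValueError("external score file needs columns (i, j, score)")
    if str(df.columns[0]).strip().lstrip("-").isdigit():
        # headerless file: what pandas took for a header was the first row
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    ii, jj, ss = (df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                  df.iloc[:, 2].to_numpy())
    scores = np.full((L, L), np.nan)
    for i1, j1, s in zip(ii.astype(int), jj.astype(int), ss.astype(float)):
        if not (1 <= i1 <= L and 1 <= j1 <= L) or i1 == j1:
            raise ValueError(f"position pair ({i1}, {j1}) out of range for "
                             f"L={L}")
        i, j = min(i1, j1) - 1, max(i1, j1) - 1
        if not np.isnan(scores[i, j]) and scores[i, j] != s:
            raise ValueError(f"conflicting duplicate entry for pair "
                             f"({i1}, {j1})")
        scores[i, j] = scores[j, i] = s
    iu, ju = np.triu_indices(L, k=1)
    missing = np.isnan(scores[iu, ju])
    if missing.any():
        if not sparse:
            raise ValueError(f"{int(missing.sum())} pairs missing from "
                             f"{path}; use sparse=True to rank them last")
        scores[np.isnan(scores)] = -np.inf
    np.fill_diagonal(scores, 0.0)
    return ScoreTable(method or meta_method or "external", scores, segments)


def read_score_tsv(path, segments) -> ScoreTable:
    """Read a score TSV written by :func:`export_scores` back into a
    :class:`ScoreTable`. The first column that is not part of the fixed
    schema is taken as the method's primary score."""
    df = pd.read_csv(path, sep="\t")
    fixed = {"pos_i", "pos_j", "res_i", "res_j", "protein_i", "protein_j",
             "class"}
    score_cols = [c for c in df.columns if c not in fixed]
    if not score_cols or "pos_i" not in df.columns:
        raise ValueError(f"{path} is not an intercov score TSV")
    method = score_cols[0]
    L = segments[-1][2]
    scores = np.zeros((L, L))
    seen = np.zeros((L, L), dtype=bool)
    ii = df["pos_i"].to_numpy(dtype=int) - 1
    jj = df["pos_j"].to_numpy(dtype=int) - 1
    ss = df[method].to_numpy(dtype=float)
    if ii.min() < 0 or jj.max() >= L:
        raise ValueError(f"positions in {path} outside [1, {L}]")
    scores[ii, jj] = ss
    scores[jj, ii] = ss
    seen[ii, jj] = seen[jj, ii] = True
    iu, ju = np.triu_indices(L, k=1)
    if not seen[iu, ju].all():
        raise ValueError(f"{path} does not list every pair for L={L}")
    return ScoreTable(method, scores, segments)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
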