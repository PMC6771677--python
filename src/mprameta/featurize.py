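"""Region featurization: sequence, motif, interval-overlap and score-table features.

Feature categories mirror the four groups used throughout the analysis:

* ``experimental`` — binary overlaps with epigenomic tracks (TFBS/DNase/
  histone-mark peak intervals) and their per-factor means, including the
  cell-type-restricted means and the shuffled-mean negative control;
* ``predicted`` — counts derived from pluggable precomputed per-region
  TF-binding score tables (e.g. deep-learning binding predictors) and
  expression-stratified variants;
* ``kmer`` — 4^k binary k-mer presence features plus sequence-composition
  scalars (#GC, longest polyA/polyT run, #distinct 5-mers) and motif-scan
  summaries;
* ``locus`` — genomic-context features (promoter/exon/intron/distal,
  conservation, closest-gene expression).

Coordinates are 0-based half-open (BED convention) throughout; overlap means
at least one shared base.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "Region",
    "kmer_features",
    "composition_features",
    "scan_motifs",
    "overlap_features",
    "score_table_features",
    "locus_features",
    "assemble_matrix",
    "sequence_feature_block",
]

_COMP = str.maketrans("ACGT", "TGCA")
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _check_seq(seq: str) -> None:
    for i, c in enumerate(seq):
        if c not in _IDX:
            raise ValueError(f"non-ACGT character {c!r} at position {i}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Region:
    """A tested element: id, sequence, optional genomic interval, cell type."""

    region_id: str
    sequence: str
    interval: tuple[str, int, int] | None = None
    cell_type: str = ""

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")
        if self.interval is not None:
            chrom, start, end = self.interval
            if end - start != len(self.sequence):
                raise ValueError(
                    f"interval length {end - start} != sequence length {len(self.sequence)}"
                )


class PWM:
    """Position weight matrix with log-odds scanning and an exact p-value.

    ``matrix`` is positions x 4 nucleotide probabilities (rows sum to 1);
    ``background`` is the 4-vector of background probabilities. Scores are
    log2 odds against the background, summed over positions. The null score
    distribution under the background model is computed exactly by dynamic
    programming over discretized per-position scores, which converts a
    p-value threshold into a score threshold.
    """

    _GRANULARITY = 1e-3

    def __init__(self, motif_id: str, matrix: np.ndarray, background=None, pseudo: float = 1e-4):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {motif_id!r}: rows must sum to 1")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if np.any(bg <= 0):
            bad = np.where(bg <= 0)[0]
            if np.any(matrix[:, bad] > 0):
                raise ValueError(
                    f"PWM {motif_id!r}: zero background probability with nonzero "
                    "matrix weight gives an infinite log-odds score"
                )
        self.motif_id = motif_id
        self.matrix = matrix
        self.background = bg / bg.sum()
        # pseudo keeps log-odds finite for zero matrix entries
        probs = (matrix + pseudo) / (1.0 + 4 * pseudo)
        self.log_odds = np.log2(probs / self.background)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=1))

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest score s with P_bg(score >= s) < p_threshold (exact DP)."""
        g = self._GRANULARITY
        iscores = np.round(self.log_odds / g).astype(np.int64)
        # DP over positions: cur[s] = P_bg(partial integer score == s)
        cur = {0: 1.0}
        for pos in range(len(self)):
            nxt: dict[int, float] = {}
            for s, pr in cur.items():
                for b in range(4):
                    key = s + int(iscores[pos, b])
                    nxt[key] = nxt.get(key, 0.0) + pr * self.background[b]
            cur = nxt
        scores = np.array(sorted(cur))
        probs = np.array([cur[s] for s in scores])
        tail = np.cumsum(probs[::-1])[::-1]  # P(score >= s)
        ok = tail < p_threshold
        if not ok.any():
            return np.inf
        # allow for the per-position rounding of scores to the DP granularity
        return float(scores[ok][0] * g - g * len(self))

    def scan(self, seq: str) -> np.ndarray:
        """Log-odds score at every start position (len(seq)-len(pwm)+1)."""
        idx = np.fromiter((_IDX[c] for c in seq), dtype=np.int64, count=len(seq))
        w = len(self)
        n = len(seq) - w + 1
        if n <= 0:
            return np.empty(0)
        windows = np.lib.stride_tricks.sliding_window_view(idx, w)
        return self.log_odds[np.arange(w), windows].sum(axis=1)


def kmer_features(seq: str, k: int = 5) -> tuple[pd.Series, int]:
    """Binary presence vector over all 4^k k-mers plus the distinct count."""
    _check_seq(seq)
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k = {k}")
    names = ["".join(p) for p in product("ACGT", repeat=k)]
    present = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    vec = pd.Series(
        [1 if kmer in present else 0 for kmer in names],
        index=[f"kmer_{kmer}" for kmer in names],
        dtype=int,
    )
    return vec, len(present)


def _longest_run(seq: str, base: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == base else 0
        best = max(best, cur)
    return best


def composition_features(seq: str) -> dict[str, int]:
    """#GC and the longest polyA / polyT run lengths."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    _check_seq(seq)
    return {
        "n_GC": sum(c in "GC" for c in seq),
        "polyA": _longest_run(seq, "A"),
        "polyT": _longest_run(seq, "T"),
    }


def scan_motifs(
    seq: str,
    pwms: list[PWM],
    p_threshold: float = 1e-4,
    window: int = 20,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Scan both strands for significant motif hits.

    A hit is a start position whose log-odds score has exact background
    p-value below ``p_threshold``. Returns the hit list (motif_id, start,
    strand, score; start on the forward strand) and the summary features
    ``n_motifs`` (hit count) and ``motif_density`` (maximum number of hit
    start positions within any ``window``-bp window).
    """
    _check_seq(seq)
    rows = []
    for pwm in pwms:
        if len(pwm) > len(seq):
            raise ValueError(
                f"motif {pwm.motif_id!r} is longer than the sequence"
            )
        thr = pwm.score_threshold(p_threshold)
        if not np.isfinite(thr):
            continue
        fwd = pwm.scan(seq)
        for start in np.where(fwd >= thr)[0]:
            rows.append((pwm.motif_id, int(start), "+", float(fwd[start])))
        rev = pwm.scan(reverse_complement(seq))
        w = len(pwm)
        for start in np.where(rev >= thr)[0]:
            # map back to forward-strand start of the covered window
            rows.append(
                (pwm.motif_id, len(seq) - int(start) - w, "-", float(rev[start]))
            )
    hits = pd.DataFrame(rows, columns=["motif_id", "start", "strand", "score"])
    starts = np.sort(hits["start"].to_numpy())
    density = 0
    for s in starts:
        density = max(density, int(((starts >= s) & (starts < s + window)).sum()))
    return hits, {"n_motifs": float(len(hits)), "motif_density": float(density)}


def _interval_overlaps(interval: tuple[str, int, int], track: pd.DataFrame) -> bool:
    chrom, start, end = interval
    t = track[track["chrom"] == chrom]
    return bool(((t["start"] < end) & (t["end"] > start)).any())


def overlap_features(
    region: Region,
    tracks: dict[str, pd.DataFrame],
    track_meta: pd.DataFrame,
    n_shuffle_draws: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Binary per-track overlaps plus per-factor mean aggregates.

    ``tracks`` maps track_id to a BED-like frame (chrom/start/end, 0-based
    half-open); ``track_meta`` has columns ``track_id, factor, cell_type``.
    Aggregates: ``<factor>_mean`` over all tracks of the factor,
    ``<factor>_cell_mean`` over the tracks matching the region's cell type,
    and ``TFBS_shuffled_mean`` — the mean binary overlap over ``n`` randomly
    chosen non-cell-type TFBS tracks (n = size of the TFBS cell set),
    averaged over ``n_shuffle_draws`` seeded draws.
    """
    if region.interval is None:
        raise ValueError(f"region {region.region_id!r} has no genomic interval")
    feats: dict[str, float] = {}
    binaries: dict[str, int] = {}
    for track_id, track in tracks.items():
        if (track["end"] <= track["start"]).any():
            raise ValueError(f"track {track_id!r} has an interval with end <= start")
        binaries[track_id] = int(_interval_overlaps(region.interval, track))
        feats[f"track_{track_id}"] = float(binaries[track_id])

    meta = track_meta.set_index("track_id")
    for factor, members in meta.groupby("factor").groups.items():
        vals = [binaries[t] for t in members if t in binaries]
        if vals:
            feats[f"{factor}_mean"] = float(np.mean(vals))
        cell_members = [
            t
            for t in members
            if t in binaries and meta.loc[t, "cell_type"] == region.cell_type
        ]
        if cell_members:
            feats[f"{factor}_cell_mean"] = float(
                np.mean([binaries[t] for t in cell_members])
            )

    tfbs = meta[meta["factor"] == "TFBS"]
    cell_n = int((tfbs["cell_type"] == region.cell_type).sum())
    pool = [
        t for t in tfbs.index if t in binaries and meta.loc[t, "cell_type"] != region.cell_type
    ]
    if cell_n > 0 and len(pool) >= cell_n:
        rng = np.random.default_rng(seed)
        draws = [
            float(np.mean([binaries[t] for t in rng.choice(pool, cell_n, replace=False)]))
            for _ in range(n_shuffle_draws)
        ]
        feats["TFBS_shuffled_mean"] = float(np.mean(draws))
    return feats


def score_table_features(
    region_ids: list[str],
    score_tables: dict[str, pd.DataFrame],
    expression: pd.Series | None = None,
    percentile: float = 90.0,
    strata_size: int = 100,
) -> pd.DataFrame:
    """Counts of strongly predicted binding factors per region.

    For each named score table (regions x factors), ``n_<name>_top`` counts
    the factors whose score for the region is strictly above that factor's
    ``percentile``-th percentile across regions. When a TPM ``expression``
    series over the factors is supplied, ``n_tf_high/med/low`` restrict the
    count to factors in the top / middle / bottom ``strata_size`` by TPM
    (computed on the first score table, mirroring the binding-predictor use).
    """
    out = pd.DataFrame(index=pd.Index(region_ids, name="region_id"))
    for name, table in score_tables.items():
        missing = set(region_ids) - set(table.index)
        if missing:
            raise ValueError(f"score table {name!r} missing regions: {sorted(missing)[:5]}")
        tab = table.loc[region_ids]
        cutoffs = np.percentile(tab.to_numpy(float), percentile, axis=0)
        above = tab.to_numpy(float) > cutoffs
        out[f"n_{name}_top"] = above.sum(axis=1)

    if expression is not None and score_tables:
        name, table = next(iter(score_tables.items()))
        tab = table.loc[region_ids]
        factors = list(tab.columns)
        missing = [f for f in factors if f not in expression.index]
        if missing:
            raise ValueError(
                f"factors missing expression values: {missing[:5]}"
            )
        tpm = expression.loc[factors]
        order = tpm.sort_values(ascending=False).index
        m = len(order)
        k = min(strata_size, m)
        high = set(order[:k])
        low = set(order[m - k :])
        mid_start = max(0, (m - k) // 2)
        mid = set(order[mid_start : mid_start + k])
        cutoffs = np.percentile(tab.to_numpy(float), percentile, axis=0)
        above = tab.to_numpy(float) > cutoffs
        for label, members in (("high", high), ("med", mid), ("low", low)):
            mask = np.array([f in members for f in factors])
            out[f"n_tf_{label}"] = (above & mask).sum(axis=1)
    return out


def locus_features(
    region: Region,
    annotations: dict[str, pd.DataFrame],
    conservation: pd.Series | None = None,
    closest_gene_tpm: float | None = None,
) -> dict[str, float]:
    """Promoter/exon/intron/distal binaries, conservation, closest-gene TPM.

    ``annotations`` maps names in {promoter, exon, intron} to BED-like
    frames. ``conservation`` is a per-base score series indexed by genomic
    position on the region's chromosome; if it does not cover the full
    interval the feature is reported as NaN (flagged missing), never zero.
    """
    if region.interval is None:
        raise ValueError(f"region {region.region_id!r} has no genomic interval")
    feats: dict[str, float] = {}
    for name in ("promoter", "exon", "intron"):
        track = annotations.get(name)
        feats[name] = (
            float(_interval_overlaps(region.interval, track))
            if track is not None and len(track)
            else 0.0
        )
    feats["distal"] = 1.0 - max(feats["promoter"], feats["exon"], feats["intron"])
    if conservation is not None:
        _, start, end = region.interval
        pos = np.arange(start, end)
        if np.isin(pos, conservation.index).all():
            feats["conservation"] = float(conservation.loc[pos].mean())
        else:
            feats["conservation"] = np.nan
    if closest_gene_tpm is not None:
        feats["closest_gene_expression"] = float(closest_gene_tpm)
    return feats


def sequence_feature_block(
    sequences: dict[str, str],
    pwms: list[PWM] | None = None,
    k: int = 5,
    p_threshold: float = 1e-4,
    score_providers: dict[str, "callable"] | None = None,
) -> pd.DataFrame:
    """All sequence-intrinsic features for a set of sequences.

    Combines k-mer presence, #distinct k-mers, composition, motif-scan
    summaries, and any pluggable per-sequence score providers (callables
    mapping a sequence to a dict of named real-valued features; the hook for
    precomputed deep-learning binding scores and DNA-shape tables).
    """
    rows = {}
    for sid, seq in sequences.items():
        vec, distinct = kmer_features(seq, k=k)
        feats = dict(vec)
        feats[f"n_distinct_{k}mers"] = distinct
        feats.update(composition_features(seq))
        if pwms:
            _, summ = scan_motifs(seq, pwms, p_threshold=p_threshold)
            feats.update(summ)
        for name, provider in (score_providers or {}).items():
            for fname, val in provider(seq).items():
                feats[f"{name}_{fname}"] = float(val)
        rows[sid] = feats
    block = pd.DataFrame.from_dict(rows, orient="index")
    block.index.name = "region_id"
    return block


def assemble_matrix(
    blocks: dict[str, pd.DataFrame],
    categories: dict[str, str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Column-bind categorized feature blocks into one FeatureMatrix.

    ``blocks`` maps block name to a regions x features frame; ``categories``
    maps block name to one of {experimental, predicted, kmer, locus}. All
    blocks must share the same region index; duplicate feature names across
    blocks are rejected. Returns the matrix and a feature -> category map.
    """
    valid = {"experimental", "predicted", "kmer", "locus"}
    names: list[str] = []
    cats: dict[str, str] = {}
    frames = []
    base_index = None
    for bname, block in blocks.items():
        cat = categories[bname]
        if cat not in valid:
            raise ValueError(f"unknown category {cat!r} for block {bname!r}")
        if base_index is None:
            base_index = block.index
        elif not block.index.equals(base_index):
            raise ValueError(f"block {bname!r} indexed by different region ids")
        dup = set(block.columns) & set(names)
        if dup:
            raise ValueError(f"duplicate feature names across blocks: {sorted(dup)[:5]}")
        names.extend(block.columns)
        cats.update({c: cat for c in block.columns})
        frames.append(block)
    matrix = pd.concat(frames, axis=1)
    category_map = pd.Series(cats, name="category").loc[matrix.columns]
    return matrix, category_map


def select_subset(
    matrix: pd.DataFrame, category_map: pd.Series, subset: str
) -> pd.DataFrame:
    """Select one of the named feature subsets; 'Full' is all categories."""
    subset_map = {
        "Experimental": ["experimental"],
        "Predicted": ["predicted"],
        "kmer": ["kmer"],
        "Locus": ["locus"],
        "Full": ["experimental", "predicted", "kmer", "locus"],
    }
    if subset not in subset_map:
        raise ValueError(f"unknown subset {subset!r}; options: {sorted(subset_map)}")
    keep = category_map[category_map.isin(subset_map[subset])].index
    return matrix[[c for c in matrix.columns if c in set(keep)]]
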