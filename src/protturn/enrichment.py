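"""Downstream interpretation: biophysical-feature enrichment and complexes.

Two analyses sit on top of the rate estimates. The first asks whether simple
sequence-derived biophysical features (length, charge fractions, hydropathy)
are enriched in the extreme tails of a protein ranking — by degradation rate
for the baseline analysis (top/bottom 5%) or by the interaction t-statistic
for oxygen effects (top/bottom 2%) — using the two-sample Kolmogorov-Smirnov
test against all other proteins. The second aggregates differential calls
over curated protein-complex memberships, reporting per-complex counts and
the fold-change range of significant subunits for complexes with at least
four measured subunits.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

# Kyte-Doolittle hydropathy, rescaled to [0, 1] via (kd + 4.5) / 9.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

POSITIVE = set("HKR")
NEGATIVE = set("DE")
CHARGED = POSITIVE | NEGATIVE

NATIVE_FEATURES = (
    "length",
    "fraction_charged",
    "fraction_negative",
    "fraction_positive",
    "hydropathy",
)


def _features_one(seq: str, protein_id: str) -> dict:
    seq = seq.upper()
    residues = [a for a in seq if a in KYTE_DOOLITTLE]
    n_unknown = len(seq) - len(residues)
    if n_unknown:
        logger.warning(
            "%s: ignoring %d non-standard residue(s)", protein_id, n_unknown
        )
    if not residues:
        raise ValueError(f"protein {protein_id}: no standard amino acids in sequence")
    n = len(residues)
    return {
        "protein_id": protein_id,
        "length": n,
        "fraction_charged": sum(a in CHARGED for a in residues) / n,
        "fraction_negative": sum(a in NEGATIVE for a in residues) / n,
        "fraction_positive": sum(a in POSITIVE for a in residues) / n,
        "hydropathy": sum((KYTE_DOOLITTLE[a] + 4.5) / 9.0 for a in residues) / n,
    }


def sequence_features(sequences) -> pd.DataFrame:
    """Compute native biophysical features per protein.

    ``sequences`` is a FASTA path or a mapping protein_id -> sequence. The
    native features are amino-acid length, the charged-residue fractions
    (charged = H/K/R/D/E, positive = H/K/R, negative = D/E) and the mean
    Kyte-Doolittle hydropathy rescaled to [0, 1]. Externally predicted
    features (e.g. disordered fraction) are merged from precomputed tables
    via :func:`merge_feature_table`, never computed here.
    """
    if isinstance(sequences, Mapping):
        items = sequences.items()
    else:
        from Bio import SeqIO

        items = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(sequences), "fasta"))
    rows = [_features_one(seq, pid) for pid, seq in items]
    if not rows:
        raise ValueError("no sequences found")
    return pd.DataFrame(rows)


def merge_feature_table(features: pd.DataFrame, extra: pd.DataFrame) -> pd.DataFrame:
    """Left-join precomputed feature columns (keyed on protein_id)."""
    if "protein_id" not in extra.columns:
        raise ValueError("precomputed feature table needs a protein_id column")
    return features.merge(extra, on="protein_id", how="left")


def rank_and_tail(values: pd.Series, tail_fraction: float) -> dict[str, pd.Index]:
    """Split a protein ranking into top/bottom tails and their backgrounds.

    ``values`` is indexed by protein_id (degradation rate for the baseline
    analysis, interaction t-statistic for the oxygen analysis). Each tail has
    max(1, floor(tail_fraction * n)) proteins; ties break by protein id so the
    split is deterministic. The background of each tail is all other proteins.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must lie in (0, 0.5)")
    values = values.dropna()
    n = len(values)
    if n < math.ceil(1.0 / tail_fraction):
        raise ValueError(
            f"too few proteins ({n}) for tail fraction {tail_fraction}"
        )
    k = max(1, int(math.floor(tail_fraction * n)))
    ordered = values.sort_index().sort_values(kind="stable")
    bottom = ordered.index[:k]
    top = ordered.index[-k:]
    return {
        "top": top,
        "bottom": bottom,
        "top_background": ordered.index[:-k],
        "bottom_background": ordered.index[k:],
        "k": k,
    }


def ks_enrichment(tail_values, background_values) -> dict:
    """Two-sided two-sample KS test of a tail against its background.

    Returns the KS statistic, p-value and the direction of the mean shift
    (+1 if the tail mean exceeds the background mean).
    """
    tail = np.asarray(tail_values, dtype=float)
    bg = np.asarray(background_values, dtype=float)
    if tail.size == 0 or bg.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(tail, bg, alternative="two-sided", method="auto")
    return {
        "ks_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "direction": int(np.sign(tail.mean() - bg.mean())) or 0,
    }


def feature_enrichment(
    features: pd.DataFrame,
    ranking: pd.Series,
    tail_fraction: float = 0.05,
    feature_names: Iterable[str] | None = None,
) -> pd.DataFrame:
    """KS enrichment of every feature in both tails of a protein ranking."""
    tails = rank_and_tail(ranking, tail_fraction)
    feats = features.set_index("protein_id")
    if feature_names is None:
        feature_names = [c for c in feats.columns if pd.api.types.is_numeric_dtype(feats[c])]
    rows = []
    for feature in feature_names:
        col = feats[feature].dropna()
        for tail in ("top", "bottom"):
            tail_ids = tails[tail].intersection(col.index)
            bg_ids = tails[f"{tail}_background"].intersection(col.index)
            if len(tail_ids) == 0 or len(bg_ids) == 0:
                logger.warning("feature %s: empty %s tail after NA removal", feature, tail)
                continue
            res = ks_enrichment(col.loc[tail_ids], col.loc[bg_ids])
            rows.append(
                {
                    "feature": feature,
                    "tail": tail,
                    "tail_fraction": tail_fraction,
                    "n_tail": len(tail_ids),
                    "n_background": len(bg_ids),
                }
                | res
            )
    return pd.DataFrame(rows)


def read_complexes(path) -> pd.DataFrame:
    """Read a complex-membership TSV: complex_id, complex_name, subunits.

    ``subunits`` is a semicolon-separated protein-id list (a simplified
    CORUM-style dialect).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"complex_id", "subunits"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"complex table missing column(s): {sorted(missing)}")
    if "complex_name" not in df.columns:
        df["complex_name"] = df["complex_id"]
    df["subunits"] = df["subunits"].map(
        lambda s: tuple(x.strip() for x in str(s).split(";") if x.strip())
    )
    if df.empty:
        raise ValueError("complex table is empty")
    return df[["complex_id", "complex_name", "subunits"]]


def complex_summaries(
    diff_records: pd.DataFrame,
    complexes: pd.DataFrame,
    min_measured: int = 4,
) -> pd.DataFrame:
    """Per-complex turnover-change summary over its measured subunits.

    A subunit counts as measured if it appears in the differential records;
    complexes with fewer than ``min_measured`` measured subunits are excluded.
    fc_min/fc_max span the linear rate fold changes (2^|log2 fc|) of the
    significant subunits.
    """
    if complexes.empty:
        raise ValueError("complex table is empty")
    if diff_records["protein_id"].duplicated().any():
        raise ValueError(
            "differential records must be one row per protein; "
            "subset to a single organ x contrast first"
        )
    by_protein = diff_records.set_index("protein_id")
    rows = []
    for _, cx in complexes.iterrows():
        subunits = cx["subunits"]
        measured = [p for p in subunits if p in by_protein.index]
        if len(measured) < min_measured:
            continue
        sub = by_protein.loc[measured]
        sig = sub.loc[sub["class"] != "ns"]
        fc = np.power(2.0, np.abs(sig["log2_fc"].to_numpy(dtype=float)))
        rows.append(
            {
                "complex_id": cx["complex_id"],
                "complex_name": cx["complex_name"],
                "n_subunits_total": len(subunits),
                "n_measured": len(measured),
                "n_significant": int(len(sig)),
                "n_faster": int((sig["class"] == "faster").sum()),
                "n_slower": int((sig["class"] == "slower").sum()),
                "fc_min": float(fc.min()) if fc.size else np.nan,
                "fc_max": float(fc.max()) if fc.size else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    logger.info(
        "complex summaries: %d of %d complexes with >= %d measured subunits",
        len(out),
        len(complexes),
        min_measured,
    )
    return out
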