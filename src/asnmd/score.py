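"""Gradient-boosted NMD-efficiency scoring.

Nine event/transcript features feed an XGBoost regressor whose response is
the gene-level expression change upon NMD inhibition (log2 scale) — a
proxy for how efficiently the decay pathway clears the isoform.  The
printed hyperparameter set (seed 321, max_depth 7, eta 0.05, 50000 rounds
with RMSE early stopping after 100, squared-error objective) is the
default; training splits 0.85:0.15 with the same seed.  ROC evaluation
yields an NMD-score cutoff by Youden's J.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import subprocess
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

FEATURE_NAMES = [
    "min_stop_pos_f",        # minimum stop-codon position fraction over isoforms
    "max_dj",                # maximum stop-to-last-junction distance (nt)
    "interaction",           # min_stop_pos_f * max_dj
    "utr3_len",              # 3'-UTR length of the original reference transcript (nt)
    "se_len",                # cassette exon length (nt)
    "se_pos_to_le",          # last exon number minus SE exon number (inclusion isoform)
    "min_stop_pos_to_end",   # minimum over isoforms of tx_len - stop_tx (nt)
    "start_exon",            # exon number containing the start codon
    "ori_utr3_mfe_per_nt",   # folding MFE of the original 3'-UTR per nt
]

DEFAULT_PARAMS: dict = {
    "seed": 321,
    "max_depth": 7,
    "eta": 0.05,
    "subsample": 0.5495662,
    "colsample_bytree": 0.8133278,
    "nthread": 1,
    "alpha": 0,
    "lambda": 1,
    "gamma": 0.2,
    "min_child_weight": 1,
    "eval_metric": "rmse",
    "objective": "reg:squarederror",
}
DEFAULT_NROUNDS = 50000
DEFAULT_EARLY_STOPPING = 100
MIN_TRAINING_ROWS = 20


class UnscorableEventError(ValueError):
    """Event lacks the junction/stop information needed for features."""


class MfeEngineUnavailableError(RuntimeError):
    """The requested external folding engine cannot be reached."""


# ---------------------------------------------------------------------------
# minimum free energy engines

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3  # minimum hairpin loop length (unpaired bases between a pair)


def _max_noncrossing_pairs(seq: str) -> int:
    """Maximum number of non-crossing Watson-Crick+GU pairs (loop >= 3)."""
    rna = seq.upper().replace("T", "U")
    n = len(rna)
    if n == 0:
        return 0
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j - 1] + 1 if (rna[i], rna[j]) in _PAIRS else 0
            best = max(best, dp[i + 1, j], dp[i, j - 1])
            for k in range(i + 1, j):
                cand = dp[i, k] + dp[k + 1, j]
                if cand > best:
                    best = cand
            dp[i, j] = best
    return int(dp[0, n - 1])


def _rnafold_mfe(seq: str) -> float:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise MfeEngineUnavailableError("RNAfold executable not found on PATH")
    rna = seq.upper().replace("T", "U")
    proc = subprocess.run(
        [exe, "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
    )
    last = proc.stdout.strip().splitlines()[-1]
    # e.g. "((((...)))) ( -5.40)"
    energy = last.rsplit("(", 1)[1].rstrip(")").strip()
    return float(energy)


def mfe_per_nt(sequence: str, engine: str = "builtin_proxy") -> float:
    """Folding minimum free energy of a sequence divided by its length.

    ``builtin_proxy`` scores the maximum non-crossing base-pairing
    (Watson-Crick + GU wobble, hairpin loop >= 3) at -1 per pair — a
    deterministic structure proxy on the same sign convention as a
    thermodynamic fold but not on its kcal/mol scale.  ``external_fold``
    delegates to the RNAfold executable and fails loudly when it is
    absent; models trained with one engine must not be scored with the
    other.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if engine == "builtin_proxy":
        return -_max_noncrossing_pairs(sequence) / len(sequence)
    if engine == "external_fold":
        return _rnafold_mfe(sequence) / len(sequence)
    raise ValueError(f"unknown MFE engine {engine!r}")


# ---------------------------------------------------------------------------
# feature extraction

def extract_features(annotation, reference_transcript, genome, mfe_engine: str = "builtin_proxy") -> dict:
    """Build the 9-feature vector for one annotated event.

    ``reference_transcript`` is the compatible transcript with an
    annotated CDS (ties broken toward the longest CDS) and supplies the
    original 3'-UTR for the length and MFE features.  Raises
    :class:`UnscorableEventError` when no isoform has a stop codon or a
    junction.
    """
    from .annotation import spliced_sequence, genomic_to_transcript
    from .events import SpliceEvent  # noqa: F401  (type context)

    orfs = [orf for _, orf in annotation.per_isoform if orf.stop_tx is not None]
    if not orfs:
        raise UnscorableEventError(f"event {annotation.event_id}: no isoform with a stop codon")
    djs = [orf.dj for orf in orfs if orf.dj is not None]
    if not djs:
        raise UnscorableEventError(f"event {annotation.event_id}: no isoform with a junction")

    min_stop_pos_f = min(orf.stop_pos_fraction for orf in orfs)
    max_dj = max(djs)
    min_stop_pos_to_end = min(orf.tx_len - orf.stop_tx for orf in orfs)

    # reference-transcript 3'-UTR: bases after its own stop codon
    ref_iso_chain = reference_transcript.exons
    ref_seq = spliced_sequence(ref_iso_chain, genome)
    start_tx = genomic_to_transcript(ref_iso_chain, reference_transcript.cds_start_genomic)
    stop_tx = None
    from .annotation import STOP_CODONS

    for pos in range(start_tx - 1, len(ref_seq) - 2, 3):
        if ref_seq[pos : pos + 3] in STOP_CODONS:
            stop_tx = pos + 3
            break
    if stop_tx is None:
        raise UnscorableEventError(
            f"event {annotation.event_id}: reference transcript has no stop codon"
        )
    utr3_seq = ref_seq[stop_tx:]
    utr3_len = len(utr3_seq)
    mfe = mfe_per_nt(utr3_seq, engine=mfe_engine) if utr3_len else 0.0

    # exon-position features on the inclusion isoform of the reference transcript
    if annotation.se_exon is None:
        raise UnscorableEventError(f"event {annotation.event_id}: SE exon unknown")
    se = annotation.se_exon
    inclusion = next(
        (iso for iso, _ in annotation.per_isoform
         if iso.form == "inclusion" and iso.source_transcript_id == reference_transcript.transcript_id),
        None,
    )
    if inclusion is None:
        inclusion = next((iso for iso, _ in annotation.per_isoform if iso.form == "inclusion"), None)
    if inclusion is None:
        raise UnscorableEventError(f"event {annotation.event_id}: no inclusion isoform")
    se_number = next(
        (num for num, exon in enumerate(inclusion.exon_chain, start=1)
         if exon.start == se.start and exon.end == se.end),
        None,
    )
    if se_number is None:
        raise UnscorableEventError(f"event {annotation.event_id}: SE exon not in inclusion chain")
    se_len = len(se)
    se_pos_to_le = len(inclusion.exon_chain) - se_number

    start_exon = 1
    cum = 0
    ref_start_tx = start_tx
    for i, exon in enumerate(ref_iso_chain, start=1):
        cum += len(exon)
        if ref_start_tx <= cum:
            start_exon = i
            break

    return {
        "event_id": annotation.event_id,
        "min_stop_pos_f": min_stop_pos_f,
        "max_dj": max_dj,
        "interaction": min_stop_pos_f * max_dj,
        "utr3_len": utr3_len,
        "se_len": se_len,
        "se_pos_to_le": se_pos_to_le,
        "min_stop_pos_to_end": min_stop_pos_to_end,
        "start_exon": start_exon,
        "ori_utr3_mfe_per_nt": mfe,
        "mfe_engine": mfe_engine,
    }


def choose_reference_transcript(compatible, index=None):
    """Compatible transcript with an annotated CDS; ties -> longest CDS span."""
    coding = [tm for tm, _ in compatible if tm.cds_start_genomic is not None]
    if not coding:
        return None
    def cds_span(tm):
        if tm.cds_end_genomic is None:
            return 0
        return abs(tm.cds_end_genomic - tm.cds_start_genomic) + 1
    return max(coding, key=lambda tm: (cds_span(tm), tm.transcript_id))


# ---------------------------------------------------------------------------
# model

@dataclass
class ScoreModel:
    booster: xgb.Booster
    params: dict
    feature_names: list[str]
    mfe_engine: str = "builtin_proxy"
    split: dict = field(default_factory=dict)
    cutoff: float | None = None
    best_iteration: int | None = None

    def schema_hash(self) -> str:
        payload = json.dumps({"features": self.feature_names, "mfe": self.mfe_engine})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(path / "booster.json"))
        meta = {
            "params": self.params,
            "feature_names": self.feature_names,
            "mfe_engine": self.mfe_engine,
            "split": self.split,
            "cutoff": self.cutoff,
            "best_iteration": self.best_iteration,
            "schema_hash": self.schema_hash(),
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ScoreModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(str(path / "booster.json"))
        meta = json.loads((path / "meta.json").read_text())
        return cls(
            booster=booster,
            params=meta["params"],
            feature_names=meta["feature_names"],
            mfe_engine=meta["mfe_engine"],
            split=meta["split"],
            cutoff=meta["cutoff"],
            best_iteration=meta["best_iteration"],
        )

    def gain_importance(self) -> dict[str, float]:
        return self.booster.get_score(importance_type="gain")


def _validate_features(features: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    X = features[FEATURE_NAMES].astype(float)
    bad = X.index[~np.isfinite(X).all(axis=1)].tolist()
    if bad:
        raise ValueError(f"non-finite feature values in rows {bad[:20]}")
    return X


def train_score_model(
    features: pd.DataFrame,
    efficiency: pd.Series | np.ndarray,
    params: dict | None = None,
    nrounds: int = DEFAULT_NROUNDS,
    early_stopping_rounds: int = DEFAULT_EARLY_STOPPING,
    test_fraction: float = 0.15,
    seed: int | None = None,
) -> ScoreModel:
    """Fit the NMD-efficiency regressor with the default hyperparameters.

    Rows split 0.85:0.15 into train/test on the model seed; the held-out
    fold drives RMSE early stopping.  All randomness is governed by the
    seed (``params['seed']`` unless overridden by ``seed``).
    """
    merged = dict(DEFAULT_PARAMS)
    if params:
        merged.update(params)
    if seed is not None:
        merged["seed"] = seed
    X = _validate_features(features)
    y = np.asarray(efficiency, dtype=float)
    if len(X) != len(y):
        raise ValueError("features and labels differ in length")
    if len(X) < MIN_TRAINING_ROWS:
        raise ValueError(f"need >= {MIN_TRAINING_ROWS} labelled rows, got {len(X)}")
    if not np.isfinite(y).all():
        raise ValueError("non-finite efficiency labels")

    idx = np.arange(len(X))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=merged["seed"], shuffle=True
    )
    dtrain = xgb.DMatrix(X.iloc[train_idx], label=y[train_idx], feature_names=FEATURE_NAMES)
    dtest = xgb.DMatrix(X.iloc[test_idx], label=y[test_idx], feature_names=FEATURE_NAMES)

    booster = xgb.train(
        merged,
        dtrain,
        num_boost_round=nrounds,
        evals=[(dtrain, "train"), (dtest, "test")],
        early_stopping_rounds=early_stopping_rounds,
        verbose_eval=False,
    )
    return ScoreModel(
        booster=booster,
        params=merged,
        feature_names=list(FEATURE_NAMES),
        split={
            "train_n": int(len(train_idx)),
            "test_n": int(len(test_idx)),
            "test_fraction": test_fraction,
            "seed": merged["seed"],
            "test_index": [int(i) for i in test_idx],
        },
        best_iteration=getattr(booster, "best_iteration", None),
    )


def predict_nmd_score(model: ScoreModel, features: pd.DataFrame, force_engine: bool = False) -> pd.Series:
    """Deterministic NMD scores for a feature table.

    Rows with any missing feature get a missing score (never 0).  A
    feature table produced with a different MFE engine than the model was
    trained with is refused unless ``force_engine``.
    """
    if "mfe_engine" in features.columns and not force_engine:
        engines = set(features["mfe_engine"].dropna().unique())
        if engines and engines != {model.mfe_engine}:
            raise ValueError(
                f"feature MFE engine {sorted(engines)} != model engine {model.mfe_engine!r}; "
                f"pass force_engine=True to override"
            )
    missing_cols = [c for c in model.feature_names if c not in features.columns]
    if missing_cols:
        raise ValueError(f"feature table missing column(s): {missing_cols}")
    X = features[model.feature_names].astype(float)
    complete = np.isfinite(X).all(axis=1)
    scores = pd.Series(np.nan, index=features.index, dtype=float)
    if complete.any():
        dm = xgb.DMatrix(X[complete], feature_names=model.feature_names)
        iteration_range = (
            (0, model.best_iteration + 1) if model.best_iteration is not None else None
        )
        preds = (
            model.booster.predict(dm, iteration_range=iteration_range)
            if iteration_range
            else model.booster.predict(dm)
        )
        scores[complete.to_numpy()] = preds
    return scores


def holdout_r2(model: ScoreModel, features: pd.DataFrame, efficiency) -> float:
    """R^2 on the model's own held-out test fold."""
    test_idx = model.split["test_index"]
    y = np.asarray(efficiency, dtype=float)[test_idx]
    yhat = predict_nmd_score(model, features.iloc[test_idx]).to_numpy()
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def evaluate_and_select_cutoff(scores, nmd_class) -> dict:
    """ROC-AUC (midrank) and the Youden-J optimal score cutoff.

    ``nmd_class`` holds binary labels (1/True = NMD).  Ties in J are
    broken toward the higher cutoff.  Single-class input is an error.
    """
    y = np.asarray([1 if c in (1, True, "NMD") else 0 for c in nmd_class])
    s = np.asarray(scores, dtype=float)
    keep = np.isfinite(s)
    y, s = y[keep], s[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s)
    j = tpr - fpr
    best = int(np.argmax(j))  # thresholds descend -> argmax picks highest cutoff on ties
    cutoff = float(thresholds[best])
    return {
        "auc": auc,
        "cutoff": cutoff,
        "roc_points": list(zip(fpr.tolist(), tpr.tolist(), thresholds.tolist())),
        "youden_j": float(j[best]),
    }
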