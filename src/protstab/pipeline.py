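"""End-to-end prediction pipeline and trained-model bundle.

Per mutation the pipeline computes, from the wild-type structure alone:

1. environment features at the site (RSA, secondary structure, side-chain
   hydrogen-bond satisfaction);
2. the distance-pattern signature of the site's environment plus the
   pharmacophore change vector (signature component input);
3. the environment-specific substitution raw score, calibrated by the
   RSA model tree;
4. the consensus epsilon-SVR prediction from the assembled 13-feature
   vector.

Training fits the calibration tree, the signature-component SVR and the
consensus SVR in sequence; the component predictions fed to the consensus
are produced out-of-fold to avoid optimistic stacking.  The fitted bundle
serialises to a single versioned JSON file carrying every array needed to
reproduce predictions bit-for-bit, plus the configuration hash of the
feature settings it was trained under.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import csm, environment, pharmacophore, predictors, sdm
from .config import Config
from .structure_io import Mutation, Structure, enumerate_mutants, parse_mutation, read_pdb

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

TRAINING_COLUMNS = ("pdb_path", "chain", "mutation", "ddg_kcal_per_mol")


@dataclass
class MutationFeatures:
    """Everything computed for one mutation before any regressor runs."""
    signature: np.ndarray       # flattened shells x 36 counts
    pharm_change: np.ndarray    # 8 signed ints
    sdm_raw: float
    rsa: float
    ss_class: str
    hbond_satisfied: bool
    env_class: sdm.EnvironmentClass

    def mcsm_input(self) -> np.ndarray:
        return np.concatenate([self.signature.astype(float), self.pharm_change.astype(float)])


@dataclass
class PredictionRecord:
    mutation: Mutation
    mcsm_pred: float
    sdm_raw: float
    sdm_calibrated: float
    consensus_pred: float       # kcal/mol, sign per convention
    rsa: float
    ss_class: str
    hbond_satisfied: bool
    classification: str         # stabilizing | destabilizing

    def to_dict(self) -> dict:
        m = self.mutation
        return {
            "chain": m.chain_id, "position": m.seq_num, "icode": m.icode,
            "wild_type": m.wt_aa, "mutant": m.mut_aa,
            "mcsm_pred": self.mcsm_pred, "sdm_raw": self.sdm_raw,
            "sdm_calibrated": self.sdm_calibrated,
            "consensus_pred": self.consensus_pred,
            "rsa": self.rsa, "ss_class": self.ss_class,
            "hbond_satisfied": self.hbond_satisfied,
            "classification": self.classification,
        }


class FeatureExtractor:
    """Computes mutation features, caching per-structure environment maps."""

    def __init__(self, config: Config | None = None, esst: sdm.ESST | None = None):
        self.config = config or Config()
        self.esst = esst
        self._env_cache: dict[int, dict] = {}

    def _environment(self, structure: Structure) -> dict:
        key = id(structure)
        if key not in self._env_cache:
            self._env_cache[key] = environment.compute_environment(structure, self.config)
        return self._env_cache[key]

    def extract(self, structure: Structure, mutation: Mutation) -> MutationFeatures:
        if self.esst is None:
            raise RuntimeError("feature extractor needs an ESST")
        env_map = self._environment(structure)
        res_key = (mutation.chain_id, mutation.seq_num, mutation.icode)
        if res_key not in env_map:
            raise KeyError(f"no residue at {mutation}")
        env = env_map[res_key]
        env_cls = sdm.environment_class(env, self.config.sdm.rsa_buried,
                                        self.config.sdm.rsa_exposed)
        signature = csm.mutation_signature(structure, mutation, self.config.csm)
        return MutationFeatures(
            signature=signature.flatten(),
            pharm_change=pharmacophore.change_vector(mutation.wt_aa, mutation.mut_aa),
            sdm_raw=sdm.sdm_raw_score(self.esst, mutation.wt_aa, mutation.mut_aa,
                                      env_cls, self.config.sdm.scale),
            rsa=env.rsa,
            ss_class=env.ss_class,
            hbond_satisfied=env.sidechain_hbond_satisfied,
            env_class=env_cls,
        )


@dataclass
class StabilityPredictor:
    """Trained bundle: ESST + calibration tree + component SVR + consensus SVR."""
    config: Config
    esst: sdm.ESST
    tree: sdm.ModelTree
    mcsm_svr: predictors.SVRModel
    consensus_svr: predictors.SVRModel
    seed: int = 0
    train_position_keys: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._extractor = FeatureExtractor(self.config, self.esst)

    def _classify(self, pred: float) -> str:
        if self.config.sign_convention == "negative_destabilizing":
            return "destabilizing" if pred < 0 else "stabilizing"
        return "destabilizing" if pred > 0 else "stabilizing"

    def predict_from_features(self, feats: MutationFeatures, mutation: Mutation
                              ) -> PredictionRecord:
        mcsm_pred = float(self.mcsm_svr.predict(feats.mcsm_input()[None, :])[0])
        sdm_cal = sdm.calibrate(self.tree, feats.sdm_raw, feats.rsa)
        vector = predictors.assemble_features(mcsm_pred, sdm_cal, feats.ss_class,
                                              feats.pharm_change)
        consensus = float(self.consensus_svr.predict(vector[None, :])[0])
        return PredictionRecord(
            mutation=mutation, mcsm_pred=mcsm_pred, sdm_raw=feats.sdm_raw,
            sdm_calibrated=sdm_cal, consensus_pred=consensus, rsa=feats.rsa,
            ss_class=feats.ss_class, hbond_satisfied=feats.hbond_satisfied,
            classification=self._classify(consensus),
        )

    def predict(self, structure: Structure, mutation: Mutation) -> PredictionRecord:
        feats = self._extractor.extract(structure, mutation)
        return self.predict_from_features(feats, mutation)

    def predict_scan(self, structure: Structure, chain_id: str, seq_num: int,
                     icode: str = "") -> list[PredictionRecord]:
        """Systematic scan: one record per non-wild-type amino acid (19)."""
        return [self.predict(structure, m)
                for m in enumerate_mutants(structure, chain_id, seq_num, icode)]

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        payload = {
            "format_version": FORMAT_VERSION,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "config_hash": self.config.hash(),
            "sign_convention": self.config.sign_convention,
            "esst": {
                "table": self.esst.table.tolist(),
                "background": self.esst.background.tolist(),
                "pseudocount": self.esst.pseudocount,
            },
            "tree": self.tree.to_dict(),
            "mcsm_svr": self.mcsm_svr.to_dict(),
            "consensus_svr": self.consensus_svr.to_dict(),
            "train_position_keys": self.train_position_keys,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "StabilityPredictor":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version "
                             f"{payload.get('format_version')!r}")
        config = Config.from_dict(payload["config"])
        esst = sdm.ESST(
            table=np.asarray(payload["esst"]["table"], dtype=float),
            background=np.asarray(payload["esst"]["background"], dtype=float),
            pseudocount=payload["esst"]["pseudocount"],
        )
        return cls(
            config=config,
            esst=esst,
            tree=sdm.ModelTree.from_dict(payload["tree"]),
            mcsm_svr=predictors.SVRModel.from_dict(payload["mcsm_svr"]),
            consensus_svr=predictors.SVRModel.from_dict(payload["consensus_svr"]),
            seed=payload["seed"],
            train_position_keys=payload["train_position_keys"],
        )


def read_training_table(path: str) -> pd.DataFrame:
    """Read and validate the training TSV (pdb_path, chain, mutation, ddg)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRAINING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"training table lacks column(s): {', '.join(missing)}")
    bad = df["ddg_kcal_per_mol"].isna()
    if bad.any():
        rows = ", ".join(str(i + 2) for i in df.index[bad][:5])  # +2: header + 1-based
        raise ValueError(f"missing ddG value(s) at line(s) {rows}")
    return df


def _compute_training_features(table: pd.DataFrame, extractor: FeatureExtractor
                               ) -> tuple[list[MutationFeatures], list[str]]:
    structures: dict[str, Structure] = {}
    feats: list[MutationFeatures] = []
    keys: list[str] = []
    for idx, row in table.iterrows():
        path = row["pdb_path"]
        if path not in structures:
            structures[path] = read_pdb(path)
        structure = structures[path]
        try:
            mutation = parse_mutation(row["mutation"], str(row["chain"]), structure)
            feats.append(extractor.extract(structure, mutation))
        except Exception as exc:
            raise ValueError(f"training table row {idx + 2}: {exc}") from exc
        keys.append(f"{path}:{row['chain']}:{mutation.seq_num}{mutation.icode}")
    return feats, keys


def train(table: pd.DataFrame, config: Config | None = None, seed: int = 0,
          esst: sdm.ESST | None = None,
          mcsm_hyperparams: dict | None = None,
          consensus_hyperparams: dict | None = None) -> StabilityPredictor:
    """Train the full bundle from a training table.

    ``table`` columns: pdb_path, chain, mutation (e.g. A7G), ddg_kcal_per_mol.
    When no ESST is given, a demonstration table is estimated from the
    package's deterministic synthetic environment-labelled sequences.
    Hyperparameters default to the cross-validated grid search; explicit
    dicts {'C','gamma','epsilon'} bypass it.
    """
    cfg = config or Config()
    if esst is None:
        from .synthetic import make_esst_observations  # local: avoid module cycle
        esst = sdm.build_esst(make_esst_observations(seed=0),
                              pseudocount=cfg.sdm.pseudocount)
    extractor = FeatureExtractor(cfg, esst)
    feats, keys = _compute_training_features(table, extractor)
    y = table["ddg_kcal_per_mol"].to_numpy(dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 training mutations")

    X_tree = np.array([[f.sdm_raw, f.rsa] for f in feats])
    X_mcsm = np.array([f.mcsm_input() for f in feats])

    # hyperparameters selected once on the full training data
    if mcsm_hyperparams is None:
        _m, info = predictors.grid_search_svr(X_mcsm, y, cfg.svr)
        mcsm_hyperparams = {k: info[k] for k in ("C", "gamma", "epsilon")}
        logger.info("signature-component hyperparameters: %s (cv r=%.3f)",
                    mcsm_hyperparams, info["cv_pearson_r"])

    # out-of-fold component predictions for consensus training
    oof_mcsm = np.empty(n)
    oof_sdm = np.empty(n)
    kf = KFold(n_splits=min(cfg.svr.stack_folds, n // 2), shuffle=True,
               random_state=seed % (2 ** 31))
    for tr, te in kf.split(X_mcsm):
        fold_tree = sdm.default_sdm_config_tree(cfg.sdm).fit(X_tree[tr], y[tr])
        oof_sdm[te] = fold_tree.predict(X_tree[te])
        fold_mcsm = predictors.SVRModel(**mcsm_hyperparams).fit(X_mcsm[tr], y[tr])
        oof_mcsm[te] = fold_mcsm.predict(X_mcsm[te])

    tree = sdm.default_sdm_config_tree(cfg.sdm).fit(X_tree, y)
    mcsm_svr = predictors.SVRModel(**mcsm_hyperparams).fit(X_mcsm, y)

    consensus_X = np.array([
        predictors.assemble_features(oof_mcsm[i], oof_sdm[i], feats[i].ss_class,
                                     feats[i].pharm_change)
        for i in range(n)
    ])
    if consensus_hyperparams is not None:
        consensus_svr = predictors.train_consensus(consensus_X, y, **consensus_hyperparams)
    else:
        consensus_svr, info = predictors.grid_search_svr(consensus_X, y, cfg.svr)
        logger.info("consensus hyperparameters: C=%s gamma=%s epsilon=%s (cv r=%.3f)",
                    info["C"], info["gamma"], info["epsilon"], info["cv_pearson_r"])

    return StabilityPredictor(
        config=cfg, esst=esst, tree=tree, mcsm_svr=mcsm_svr,
        consensus_svr=consensus_svr, seed=seed,
        train_position_keys=sorted(set(keys)),
    )


def evaluate(predictor: StabilityPredictor, table: pd.DataFrame,
             outlier_frac: float = 0.1):
    """Apply a trained bundle to a mutation table; returns (EvalReport,
    predictions array, position keys).  Warns when the table shares mutated
    positions with the bundle's training set (the split is then not blind)."""
    from .evaluation import outlier_removal_eval, position_overlap

    extractor = FeatureExtractor(predictor.config, predictor.esst)
    structures: dict[str, Structure] = {}
    preds = []
    keys = []
    for idx, row in table.iterrows():
        path = row["pdb_path"]
        if path not in structures:
            structures[path] = read_pdb(path)
        structure = structures[path]
        mutation = parse_mutation(row["mutation"], str(row["chain"]), structure)
        feats = extractor.extract(structure, mutation)
        preds.append(predictor.predict_from_features(feats, mutation).consensus_pred)
        keys.append(f"{path}:{row['chain']}:{mutation.seq_num}{mutation.icode}")
    overlap = position_overlap(predictor.train_position_keys, keys)
    if overlap:
        logger.warning("evaluation set shares %d mutated position(s) with the "
                       "training set; the split is not blind", len(overlap))
    obs = table["ddg_kcal_per_mol"].to_numpy(dtype=float)
    report = outlier_removal_eval(np.asarray(preds), obs, frac=outlier_frac)
    return report, np.asarray(preds), keys
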