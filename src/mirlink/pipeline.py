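"""End-to-end orchestration: embed -> filter -> augment -> classify -> rank.

One :class:`PipelineConfig` drives every stage. A single master seed fans
out deterministically to per-stage child seeds (stage-name hash, counter
free), so adding or reordering stages never perturbs another stage's
randomness and a rerun with the same config reproduces every TSV/CSV
artifact byte for byte. Every written artifact carries a provenance
header (config JSON + master seed) sufficient to re-derive it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import RobustScaler

from . import autoencoder as ae_mod
from . import discovery, embedding, lstm, negatives, sequence_io

logger = logging.getLogger("mirlink")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the master seed."""
    return (master_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """All knobs for a full run; serialized into artifact provenance."""

    mirna_fasta: str = "miRNA.fa"
    gene_fasta: str = "genes.fa"
    positives_tsv: str = "positives.tsv"
    outdir: str = "mirlink_out"

    # embedding
    k: int = embedding.DEFAULT_K
    dimension: int = embedding.DEFAULT_DIMENSION
    window: int = embedding.DEFAULT_WINDOW
    embed_epochs: int = embedding.DEFAULT_EPOCHS

    # negative filtering
    epsilon: float = negatives.DEFAULT_EPSILON
    filter_mode: str = "all"

    # autoencoder
    latent_dim: int = ae_mod.DEFAULT_LATENT_DIM
    ae_epochs: int = ae_mod.DEFAULT_AE_EPOCHS
    ae_batch: int = ae_mod.DEFAULT_AE_BATCH
    ae_lr: float = ae_mod.DEFAULT_AE_LR
    ae_split: float = ae_mod.DEFAULT_AE_SPLIT
    feature_mode: str = "original_plus_latent"

    # classifier
    folds: int = lstm.DEFAULT_FOLDS
    cls_epochs: int = lstm.DEFAULT_CLS_EPOCHS
    cls_batch: int = lstm.DEFAULT_CLS_BATCH
    cls_lr: float = lstm.DEFAULT_CLS_LR
    threshold: float = lstm.DEFAULT_THRESHOLD
    input_shaping: str = "aligned"
    paper_mode: bool = False

    # discovery
    top_k: int = discovery.DEFAULT_TOP_K
    chunk_size: int = discovery.DEFAULT_CHUNK

    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def cv_config(self) -> lstm.CVConfig:
        return lstm.CVConfig(
            folds=self.folds,
            mode=self.feature_mode,  # type: ignore[arg-type]
            latent_dim=self.latent_dim,
            ae_epochs=self.ae_epochs,
            ae_batch=self.ae_batch,
            ae_lr=self.ae_lr,
            ae_split=self.ae_split,
            cls_epochs=self.cls_epochs,
            cls_batch=self.cls_batch,
            cls_lr=self.cls_lr,
            shaping=self.input_shaping,  # type: ignore[arg-type]
            threshold=self.threshold,
            paper_mode=self.paper_mode,
            seed=stage_seed(self.seed, "cross_validate"),
        )


@dataclass
class PipelineArtifacts:
    """In-memory results plus the paths of everything written."""

    embeddings: embedding.EmbeddingTable
    thresholds: negatives.DistanceThresholds
    pair_set: negatives.LabeledPairSet
    autoencoder: ae_mod.AutoencoderModel
    classifier: lstm.ClassifierModel
    report: lstm.EvalReport
    predictions: list[discovery.RankedPrediction]
    paths: dict[str, Path] = field(default_factory=dict)


def _provenance_header(config: PipelineConfig, stage: str) -> str:
    return (
        f"# mirlink stage={stage} master_seed={config.seed} "
        f"config={config.to_json()}\n"
    )


def _write_text(path: Path, header: str, body: str) -> None:
    path.write_text(header + body, encoding="utf-8")


def run_full(config: PipelineConfig) -> PipelineArtifacts:
    """Execute all stages in order on the configured inputs.

    Stage order: sequence embedding; distance-threshold negative
    construction; autoencoder feature training; cross-validated LSTM
    evaluation; final-model training on the full balanced set; ranked
    discovery over the unknown pool.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # ---- stage: load inputs ------------------------------------------------
    mirnas = sequence_io.read_fasta(config.mirna_fasta, sequence_io.SequenceKind.MIRNA)
    genes = sequence_io.read_fasta(config.gene_fasta, sequence_io.SequenceKind.GENE)
    raw_pairs = sequence_io.read_pairs(config.positives_tsv)
    positives, n_dropped = sequence_io.join_pairs_to_sequences(raw_pairs, mirnas, genes)
    logger.info(
        "inputs: %d miRNAs, %d genes, %d positive pairs (%d dropped)",
        len(mirnas), len(genes), len(positives), n_dropped,
    )

    # ---- stage: embedding --------------------------------------------------
    docs = embedding.build_corpus(list(mirnas) + list(genes), k=config.k)
    table = embedding.train_embedding(
        docs,
        dimension=config.dimension,
        window=config.window,
        epochs=config.embed_epochs,
        seed=stage_seed(config.seed, "embedding"),
    )
    paths["embeddings"] = outdir / "embeddings.tsv"
    with open(paths["embeddings"], "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(config, "embedding"))
    with open(paths["embeddings"], "a", encoding="utf-8") as fh:
        for did, vec in table.vectors.items():
            fh.write(did + "\t" + "\t".join(repr(float(x)) for x in vec) + "\n")
    logger.info("embedding: %d sequence vectors of dimension %d",
                len(table.vectors), table.dimension)

    # ---- stage: negative filtering ----------------------------------------
    universe = discovery.build_unknown_pool(mirnas, genes, positives.with_label(None))
    pair_set, thresholds = negatives.build_labeled_set(
        positives,
        universe,
        table,
        seed=stage_seed(config.seed, "negatives"),
        epsilon=config.epsilon,
        mode=config.filter_mode,  # type: ignore[arg-type]
    )
    logger.info(
        "labeled set: %d positives + %d negatives",
        len(pair_set.positives), len(pair_set.negatives),
    )
    paths["dataset"] = outdir / "dataset.tsv"
    body = "".join(f"{m}\t{g}\t{lab}\n" for m, g, lab in pair_set.pairs)
    _write_text(paths["dataset"], _provenance_header(config, "negatives"), body)
    paths["thresholds"] = outdir / "thresholds.json"
    paths["thresholds"].write_text(json.dumps(
        {"provenance": {"master_seed": config.seed,
                        "config": json.loads(config.to_json())},
         **thresholds.as_dict()}, indent=2))
    paths["covariance"] = outdir / "covariance.npy"
    np.save(paths["covariance"], thresholds.covariance)

    # ---- stage: cross-validated evaluation ---------------------------------
    report = lstm.cross_validate(pair_set, table, config.cv_config())
    paths["evalreport_csv"] = outdir / "evalreport.csv"
    records = [r.as_dict() for r in report.rows] + [report.average.as_dict()]
    csv_body = pd.DataFrame(records).to_csv(index=False, float_format="%.6f")
    _write_text(paths["evalreport_csv"],
                _provenance_header(config, "cross_validate"), csv_body)
    paths["evalreport_json"] = outdir / "evalreport.json"
    paths["evalreport_json"].write_text(report.to_json())
    logger.info("cross-validation: mean accuracy %.4f, mean AUC %.4f",
                report.average.accuracy, report.average.auc)

    # ---- stage: final model on the full balanced set -----------------------
    keys = [(m, g) for m, g, _ in pair_set.pairs]
    X_raw = embedding.embed_pairs(table, keys)
    y = pair_set.labels
    ae_model, _hist = ae_mod.train_autoencoder(
        X_raw,
        latent_dim=config.latent_dim,
        epochs=config.ae_epochs,
        batch=config.ae_batch,
        lr=config.ae_lr,
        split=config.ae_split,
        seed=stage_seed(config.seed, "autoencoder_final"),
    )
    F = ae_mod.augment_features(X_raw, ae_model, config.feature_mode)  # type: ignore[arg-type]
    if config.feature_mode == "original_plus_latent":
        layout = (table.dimension, table.dimension, config.latent_dim)
    else:
        layout = (config.latent_dim,)
    clf = lstm.fit(
        F, y,
        epochs=config.cls_epochs,
        batch=config.cls_batch,
        lr=config.cls_lr,
        seed=stage_seed(config.seed, "classifier_final"),
        shaping=config.input_shaping,  # type: ignore[arg-type]
        layout=layout,
    )
    paths["autoencoder"] = outdir / "autoencoder.npz"
    save_autoencoder(ae_model, paths["autoencoder"])
    paths["classifier"] = outdir / "classifier.npz"
    save_classifier(clf, paths["classifier"])

    # ---- stage: discovery --------------------------------------------------
    pool_iter = discovery.iter_unknown_pool(mirnas, genes,
                                            pair_set.positives.with_label(None))
    preds = discovery.rank_pairs(
        pool_iter, clf, ae_model, table,
        k=config.top_k,
        mode=config.feature_mode,  # type: ignore[arg-type]
        chunk_size=config.chunk_size,
    )
    paths["predictions"] = outdir / "predictions.tsv"
    body = "rank\tmiRNA_id\tgene_id\tscore\n" + "".join(
        f"{p.rank}\t{p.mirna_id}\t{p.gene_id}\t{p.score:.6f}\n" for p in preds
    )
    _write_text(paths["predictions"], _provenance_header(config, "discovery"), body)
    logger.info("discovery: wrote top-%d predictions", len(preds))

    return PipelineArtifacts(
        embeddings=table,
        thresholds=thresholds,
        pair_set=pair_set,
        autoencoder=ae_model,
        classifier=clf,
        report=report,
        predictions=preds,
        paths=paths,
    )


def sweep_latent(
    config: PipelineConfig,
    sizes: list[int],
    modes: tuple[str, ...] = ("latent_only", "original_plus_latent"),
) -> pd.DataFrame:
    """Mean CV AUC per (latent size, feature mode); one run per cell.

    Reuses the embedding and labeled set across cells (they do not depend
    on latent size or mode); each cell re-runs autoencoder training and
    cross-validated classification with a seed fanned out from the master.
    """
    if not sizes:
        raise ValueError("sizes must be nonempty")
    mirnas = sequence_io.read_fasta(config.mirna_fasta, sequence_io.SequenceKind.MIRNA)
    genes = sequence_io.read_fasta(config.gene_fasta, sequence_io.SequenceKind.GENE)
    raw_pairs = sequence_io.read_pairs(config.positives_tsv)
    positives, _ = sequence_io.join_pairs_to_sequences(raw_pairs, mirnas, genes)
    docs = embedding.build_corpus(list(mirnas) + list(genes), k=config.k)
    table = embedding.train_embedding(
        docs, dimension=config.dimension, window=config.window,
        epochs=config.embed_epochs, seed=stage_seed(config.seed, "embedding"),
    )
    universe = discovery.build_unknown_pool(mirnas, genes, positives.with_label(None))
    pair_set, _ = negatives.build_labeled_set(
        positives, universe, table,
        seed=stage_seed(config.seed, "negatives"),
        epsilon=config.epsilon, mode=config.filter_mode,  # type: ignore[arg-type]
    )
    cells = {}
    for mode in modes:
        for size in sizes:
            cv = config.cv_config()
            cv.mode = mode  # type: ignore[assignment]
            cv.latent_dim = size
            cv.seed = stage_seed(config.seed, f"sweep:{mode}:{size}")
            report = lstm.cross_validate(pair_set, table, cv)
            cells[(size, mode)] = report.average.auc
            logger.info("sweep latent=%d mode=%s: mean AUC %.4f",
                        size, mode, report.average.auc)
    df = pd.DataFrame(
        {mode: [cells[(s, mode)] for s in sizes] for mode in modes},
        index=pd.Index(sizes, name="latent_size"),
    )
    return df


# --------------------------------------------------------------------------
# model checkpoints (single-file npz containers)
# --------------------------------------------------------------------------

def save_autoencoder(model: ae_mod.AutoencoderModel, path) -> None:
    arrays = {
        "latent_dim": np.array(model.latent_dim),
        "input_dim": np.array(model.input_dim),
        "scaling_mins": model.scaling.mins,
        "scaling_maxs": model.scaling.maxs,
        "config_json": np.frombuffer(
            json.dumps(model.config).encode(), dtype=np.uint8
        ),
        "n_layers": np.array(len(model.encoder_weights)),
    }
    for i, (W, b) in enumerate(zip(model.encoder_weights, model.encoder_biases)):
        arrays[f"We{i}"], arrays[f"be{i}"] = W, b
    for i, (W, b) in enumerate(zip(model.decoder_weights, model.decoder_biases)):
        arrays[f"Wd{i}"], arrays[f"bd{i}"] = W, b
    np.savez(path, **arrays)


def load_autoencoder(path) -> ae_mod.AutoencoderModel:
    data = np.load(path)
    n = int(data["n_layers"])
    return ae_mod.AutoencoderModel(
        encoder_weights=[data[f"We{i}"] for i in range(n)],
        encoder_biases=[data[f"be{i}"] for i in range(n)],
        decoder_weights=[data[f"Wd{i}"] for i in range(n)],
        decoder_biases=[data[f"bd{i}"] for i in range(n)],
        latent_dim=int(data["latent_dim"]),
        input_dim=int(data["input_dim"]),
        scaling=ae_mod.MinMaxScaling(data["scaling_mins"], data["scaling_maxs"]),
        config=json.loads(bytes(data["config_json"]).decode()),
    )


def save_classifier(model: lstm.ClassifierModel, path) -> None:
    arrays = {
        "hidden": np.array(model.hidden),
        "input_width": np.array(model.input_width),
        "step_width": np.array(model.step_width),
        "shaping": np.frombuffer(model.shaping.encode(), dtype=np.uint8),
        "head_pooling": np.frombuffer(model.head_pooling.encode(), dtype=np.uint8),
        "n_steps": np.array(model.n_steps),
        "layout": np.array(model.layout if model.layout is not None else [],
                           dtype=np.int64),
        "head_w": model.head_w,
        "head_b": np.array(model.head_b),
        "n_layers": np.array(len(model.W)),
        "config_json": np.frombuffer(
            json.dumps(model.config).encode(), dtype=np.uint8
        ),
    }
    for i, (W, b) in enumerate(zip(model.W, model.b)):
        arrays[f"W{i}"], arrays[f"b{i}"] = W, b
    if model.scaler is not None:
        arrays["scaler_center"] = model.scaler.center_
        arrays["scaler_scale"] = model.scaler.scale_
    np.savez(path, **arrays)


def load_classifier(path) -> lstm.ClassifierModel:
    data = np.load(path)
    n = int(data["n_layers"])
    scaler = None
    if "scaler_center" in data:
        scaler = RobustScaler()
        scaler.center_ = data["scaler_center"]
        scaler.scale_ = data["scaler_scale"]
        scaler.n_features_in_ = data["scaler_center"].size
    layout = tuple(int(x) for x in data["layout"]) if "layout" in data else ()
    return lstm.ClassifierModel(
        W=[data[f"W{i}"] for i in range(n)],
        b=[data[f"b{i}"] for i in range(n)],
        head_w=data["head_w"],
        head_b=float(data["head_b"]),
        hidden=int(data["hidden"]),
        input_width=int(data["input_width"]),
        shaping=bytes(data["shaping"]).decode(),  # type: ignore[arg-type]
        step_width=int(data["step_width"]),
        scaler=scaler,
        layout=layout or None,
        n_steps=int(data["n_steps"]) if "n_steps" in data
        else lstm.DEFAULT_ALIGNED_STEPS,
        head_pooling=bytes(data["head_pooling"]).decode()
        if "head_pooling" in data else "last",
        config=json.loads(bytes(data["config_json"]).decode()),
    )
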