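"""Feature spaces for tumor-to-normal correlation.

Three representations of an expression profile:

* ``varying_genes`` — the top-K genes by expression variance across the
  tumor cohort (default K = 5000); the "embedding" is the raw sub-vector.
* ``pca`` — the leading principal components (default 64) of centered
  log2(TPM+1) profiles.
* ``autoencoder`` — the 64-unit bottleneck of a symmetric fully-connected
  autoencoder trained on TPM profiles (internally log2(TPM+1) then
  per-gene min-max scaled to [0, 1]; the scaling constants are part of the
  fitted model).

All three are wrapped in :class:`EmbeddingModel`, which carries the gene
universe, the fitted state, and a serialization round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .autoencoder import AutoencoderNet
from .io import CountMatrix

FORMAT_VERSION = 1


class FeatureSpaceError(ValueError):
    pass


@dataclass
class TrainingCurve:
    """Per-epoch mean squared reconstruction error, training and held-out."""

    train: list[float]
    test: list[float]

    def __post_init__(self) -> None:
        if len(self.train) != len(self.test):
            raise FeatureSpaceError("train/test curves differ in length")
        if any(v < 0 for v in self.train + self.test):
            raise FeatureSpaceError("negative MSE in training curve")

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {"epoch": range(1, len(self.train) + 1), "train_mse": self.train, "test_mse": self.test}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class EmbeddingModel:
    """A fitted map from an expression profile to a feature vector."""

    kind: str  # varying_genes | pca | autoencoder
    gene_ids: list[str]
    dim: int
    arrays: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    fit_metadata: dict = field(default_factory=dict)
    _net: AutoencoderNet | None = field(default=None, repr=False)

    #: expression unit each kind expects at encode time
    INPUT_UNIT = {"varying_genes": "log2_tpm_plus1", "pca": "log2_tpm_plus1", "autoencoder": "tpm"}

    def save(self, path: str | Path) -> None:
        header = {
            "format_version": FORMAT_VERSION,
            "kind": self.kind,
            "dim": self.dim,
            "gene_ids": self.gene_ids,
            "meta": self.meta,
            "fit_metadata": self.fit_metadata,
        }
        arrays = dict(self.arrays)
        if self.kind == "autoencoder":
            arrays.update(self._net.state_arrays())
        np.savez(path, __header__=np.array(json.dumps(header)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path) as z:
            header = json.loads(str(z["__header__"]))
            arrays = {k: z[k] for k in z.files if k != "__header__"}
        if header.get("format_version") != FORMAT_VERSION:
            raise FeatureSpaceError(f"unsupported model format {header.get('format_version')}")
        model = cls(
            kind=header["kind"],
            gene_ids=list(header["gene_ids"]),
            dim=int(header["dim"]),
            meta=header["meta"],
            fit_metadata=header["fit_metadata"],
        )
        if model.kind == "autoencoder":
            net = AutoencoderNet(
                n_input=len(model.gene_ids),
                hidden=int(model.meta["hidden"]),
                bottleneck=model.dim,
                dropout=float(model.meta["dropout"]),
                leaky_slope=float(model.meta["leaky_slope"]),
                rng=np.random.default_rng(0),
            )
            net.load_state_arrays(arrays)
            model._net = net
            model.arrays = {k: arrays[k] for k in ("gene_min", "gene_max") if k in arrays}
        else:
            model.arrays = arrays
        return model


def select_top_varying_genes(
    m: CountMatrix, cohort: Sequence[str], k: int = 5000
) -> EmbeddingModel:
    """Rank genes by variance across ``cohort`` and keep the top ``k``.

    Ties are broken by gene id (lexicographic) so the selection is
    deterministic.
    """
    if len(cohort) == 0:
        raise FeatureSpaceError("empty cohort for variance ranking")
    if m.unit != "log2_tpm_plus1":
        raise FeatureSpaceError(f"expected log2_tpm_plus1, got {m.unit}")
    sub = m.subset_samples(list(cohort))
    var = sub.values.to_numpy().var(axis=1, ddof=1) if len(cohort) > 1 else np.zeros(m.n_genes)
    genes = np.asarray(m.gene_ids)
    # descending variance, ascending gene id on ties
    order = np.lexsort((genes, -var))
    k_eff = min(k, m.n_genes)
    selected = genes[order][:k_eff]
    return EmbeddingModel(
        kind="varying_genes",
        gene_ids=list(m.gene_ids),
        dim=k_eff,
        arrays={"selected": np.asarray(selected, dtype="U"), "variance": var[order][:k_eff]},
        meta={"k": k},
        fit_metadata={"cohort_size": len(cohort)},
    )


def fit_pca_embedding(m: CountMatrix, n_components: int = 64) -> EmbeddingModel:
    """Centered per-gene PCA of log2(TPM+1) profiles."""
    if m.unit != "log2_tpm_plus1":
        raise FeatureSpaceError(f"expected log2_tpm_plus1, got {m.unit}")
    if n_components >= m.n_samples:
        raise FeatureSpaceError(
            f"n_components ({n_components}) must be < n_samples ({m.n_samples})"
        )
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return EmbeddingModel(
        kind="pca",
        gene_ids=list(m.gene_ids),
        dim=n_components,
        arrays={
            "components": pca.components_,
            "mean": pca.mean_,
            "explained_variance_ratio": pca.explained_variance_ratio_,
        },
        meta={"n_components": n_components},
        fit_metadata={"n_samples": m.n_samples},
    )


@dataclass
class AutoencoderParams:
    bottleneck: int = 64
    hidden: int = 512
    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 0.0002
    dropout: float = 0.2
    leaky_slope: float = 0.2
    split: float = 0.8
    seed: int = 0


def train_autoencoder(
    m: CountMatrix,
    params: AutoencoderParams | None = None,
    site_labels: Sequence[str] | None = None,
) -> tuple[EmbeddingModel, TrainingCurve]:
    """Train the bottleneck autoencoder on TPM profiles.

    Input TPM values are log2(x+1)-transformed and min-max scaled per gene
    to [0, 1]; the scaling constants are stored in the model so that
    :func:`encode` applies the identical preprocessing.  Samples are split
    80/20 into train/held-out sets, stratified by ``site_labels`` when
    provided so rare sites appear in training.
    """
    params = params or AutoencoderParams()
    if m.unit != "tpm":
        raise FeatureSpaceError(f"autoencoder expects tpm input, got {m.unit}")
    if params.bottleneck >= m.n_genes:
        raise FeatureSpaceError("bottleneck must be smaller than the input dimension")
    rng = np.random.default_rng(params.seed)
    X = np.log2(m.values.to_numpy(dtype=float).T + 1.0)  # samples x genes
    gmin = X.min(axis=0)
    gmax = X.max(axis=0)
    span = np.where(gmax > gmin, gmax - gmin, 1.0)
    Xs = (X - gmin) / span

    n = Xs.shape[0]
    if site_labels is not None:
        train_idx = []
        test_idx = []
        labels = np.asarray(site_labels)
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            idx = rng.permutation(idx)
            cut = max(1, int(round(params.split * len(idx))))
            train_idx.extend(idx[:cut])
            test_idx.extend(idx[cut:])
        train_idx = np.sort(np.array(train_idx, dtype=int))
        test_idx = np.sort(np.array(test_idx, dtype=int))
    else:
        perm = rng.permutation(n)
        cut = max(1, int(round(params.split * n)))
        train_idx, test_idx = np.sort(perm[:cut]), np.sort(perm[cut:])
    if len(test_idx) == 0:  # tiny data: evaluate held-out loss on train
        test_idx = train_idx

    net = AutoencoderNet(
        n_input=m.n_genes,
        hidden=params.hidden,
        bottleneck=params.bottleneck,
        dropout=params.dropout,
        leaky_slope=params.leaky_slope,
        rng=rng,
    )
    Xtr, Xte = Xs[train_idx], Xs[test_idx]
    train_curve, test_curve = [], []
    for _ in range(params.epochs):
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(order), params.batch_size):
            batch = Xtr[order[start : start + params.batch_size]]
            if len(batch) < 2:
                continue  # batch statistics undefined for a single sample
            losses.append(net.train_batch(batch, lr=params.learning_rate))
        train_curve.append(float(np.mean(losses)))
        test_curve.append(net.eval_loss(Xte))
        if not np.isfinite(train_curve[-1]):
            raise FeatureSpaceError(
                f"training diverged at epoch {len(train_curve)} (loss={train_curve[-1]})"
            )

    model = EmbeddingModel(
        kind="autoencoder",
        gene_ids=list(m.gene_ids),
        dim=params.bottleneck,
        arrays={"gene_min": gmin, "gene_max": gmax},
        meta={
            "hidden": params.hidden,
            "dropout": params.dropout,
            "leaky_slope": params.leaky_slope,
        },
        fit_metadata={
            "seed": params.seed,
            "epochs": params.epochs,
            "batch_size": params.batch_size,
            "learning_rate": params.learning_rate,
            "train_indices": [int(i) for i in train_idx],
            "test_indices": [int(i) for i in test_idx],
            "final_train_mse": train_curve[-1],
            "final_test_mse": test_curve[-1],
        },
        _net=net,
    )
    return model, TrainingCurve(train=train_curve, test=test_curve)


def encode(model: EmbeddingModel, m: CountMatrix) -> pd.DataFrame:
    """Map each sample of ``m`` to the model's feature space (samples x dim).

    Deterministic: dropout off, batch normalization uses stored running
    statistics.
    """
    expected_unit = EmbeddingModel.INPUT_UNIT[model.kind]
    if m.unit != expected_unit:
        raise FeatureSpaceError(f"{model.kind} encode expects {expected_unit}, got {m.unit}")
    missing = set(model.gene_ids) - set(m.gene_ids)
    if missing:
        raise FeatureSpaceError(f"input matrix lacks model genes: {sorted(missing)[:5]}")
    sub = m.values.loc[model.gene_ids, :]
    if model.kind == "varying_genes":
        feats = sub.loc[list(model.arrays["selected"]), :].to_numpy(dtype=float).T
    elif model.kind == "pca":
        X = sub.to_numpy(dtype=float).T
        feats = (X - model.arrays["mean"]) @ model.arrays["components"].T
    elif model.kind == "autoencoder":
        X = np.log2(sub.to_numpy(dtype=float).T + 1.0)
        gmin, gmax = model.arrays["gene_min"], model.arrays["gene_max"]
        span = np.where(gmax > gmin, gmax - gmin, 1.0)
        feats = model._net.encode((X - gmin) / span)
    else:
        raise FeatureSpaceError(f"unknown model kind {model.kind!r}")
    return pd.DataFrame(feats, index=m.sample_ids)
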