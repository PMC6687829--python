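"""HDF5 serialization of fitted decoders (weights + scalers + config).

A saved model is self-contained: loading reconstructs a decoder whose
``evaluate_part`` / ``reconstruct`` behave identically to the fitted
original (network parameters, batch-norm running statistics and the robust
scalers are all stored).
"""

from __future__ import annotations

import h5py
import numpy as np

from .decoders import (ConvClassifierDecoder, LinearReconstructionDecoder,
                       NetReconstructionDecoder)
from .linear import DecoderWeights
from .nnet.classifier import ClassifierConfig, ConvClassifier
from .nnet.layers import BatchNorm
from .nnet.reconstruction import ReconNetConfig, ReconstructionNet
from .preprocessing import RobustScaler


def _save_scalers(f, dec) -> None:
    g = f.create_group("scalers")
    g.create_dataset("eeg_medians", data=np.atleast_1d(dec.eeg_scaler.medians))
    g.create_dataset("eeg_iqrs", data=np.atleast_1d(dec.eeg_scaler.iqrs))
    g.create_dataset("env_median", data=float(dec.env_scaler.medians))
    g.create_dataset("env_iqr", data=float(dec.env_scaler.iqrs))


def _load_scalers(f, dec) -> None:
    g = f["scalers"]
    dec.eeg_scaler = RobustScaler(medians=g["eeg_medians"][()],
                                  iqrs=g["eeg_iqrs"][()])
    dec.env_scaler = RobustScaler(medians=float(g["env_median"][()]),
                                  iqrs=float(g["env_iqr"][()]))


def _save_net(f, net) -> None:
    g = f.create_group("params")
    for i, p in enumerate(net.parameters()):
        g.create_dataset(f"{i:03d}_{p.name}", data=p.value)
    r = f.create_group("running")
    for i, layer in enumerate(net.net.layers):
        if isinstance(layer, BatchNorm):
            r.create_dataset(f"{i:03d}_mean", data=layer.running_mean)
            r.create_dataset(f"{i:03d}_var", data=layer.running_var)


def _load_net(f, net) -> None:
    g = f["params"]
    for i, p in enumerate(net.parameters()):
        p.value[...] = g[f"{i:03d}_{p.name}"][()]
    r = f["running"]
    for i, layer in enumerate(net.net.layers):
        if isinstance(layer, BatchNorm):
            layer.running_mean = r[f"{i:03d}_mean"][()]
            layer.running_var = r[f"{i:03d}_var"][()]


def save_decoder(dec, path) -> None:
    with h5py.File(path, "w") as f:
        if isinstance(dec, LinearReconstructionDecoder):
            f.attrs["kind"] = "lsq"
            f.attrs["n_lags"] = dec.n_lags
            g = f.create_group("linear")
            g.create_dataset("w", data=dec.weights.w)
            g.attrs["n_channels"] = dec.weights.n_channels
            g.attrs["n_lags"] = dec.weights.n_lags
            g.attrs["lambda"] = (np.nan if dec.weights.lambda_selected is None
                                 else dec.weights.lambda_selected)
        elif isinstance(dec, NetReconstructionDecoder):
            f.attrs["kind"] = "dnn-corr"
            f.attrs["n_lags"] = dec.n_lags
            f.attrs["input_dim"] = dec.model.cfg.input_dim
            _save_net(f, dec.model)
        elif isinstance(dec, ConvClassifierDecoder):
            f.attrs["kind"] = "dnn-clf"
            cfg = dec.model.cfg
            f.attrs["n_eeg_channels"] = cfg.n_eeg_channels
            f.attrs["conv1_out"] = cfg.conv1_out
            f.attrs["dropout"] = cfg.dropout
            _save_net(f, dec.model)
        else:
            raise TypeError(f"cannot serialize {type(dec).__name__}")
        _save_scalers(f, dec)


def load_decoder(path):
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        if kind == "lsq":
            dec = LinearReconstructionDecoder(n_lags=int(f.attrs["n_lags"]))
            g = f["linear"]
            lam = float(g.attrs["lambda"])
            dec.weights = DecoderWeights(
                w=g["w"][()], n_channels=int(g.attrs["n_channels"]),
                n_lags=int(g.attrs["n_lags"]),
                lambda_selected=None if np.isnan(lam) else lam,
            )
        elif kind == "dnn-corr":
            dec = NetReconstructionDecoder(n_lags=int(f.attrs["n_lags"]))
            cfg = ReconNetConfig(input_dim=int(f.attrs["input_dim"]))
            dec.model = ReconstructionNet(cfg, seed=0)
            _load_net(f, dec.model)
        elif kind == "dnn-clf":
            dec = ConvClassifierDecoder(
                conv1_out=int(f.attrs["conv1_out"]),
                dropout=float(f.attrs["dropout"]),
            )
            cfg = ClassifierConfig(
                n_eeg_channels=int(f.attrs["n_eeg_channels"]),
                conv1_out=int(f.attrs["conv1_out"]),
                dropout=float(f.attrs["dropout"]),
            )
            dec.model = ConvClassifier(cfg, seed=0)
            _load_net(f, dec.model)
        else:
            raise ValueError(f"unknown decoder kind {kind!r}")
        _load_scalers(f, dec)
    return dec
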