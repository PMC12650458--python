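"""Three-branch 1D/2D convolutional classifier with grouped
modality-frequency attention.

Nine feature streams enter per window: four within-EEG GC matrices (one
per rhythm band), one fNIRS time-series block (HbO2 and HbR rows
stacked), and four cross-modal GC matrices (one per band). Each branch
encodes its streams with three stride-1, same-padded convolutions
(32/64/128 filters, no pooling) followed by a 128-unit fully connected
layer, producing a 9 x 128 deep feature X per window.

The attention module squeezes X to a 9-vector descriptor by global
average pooling over the feature axis, splits it into the 4/1/4
modality groups, and maps each group through a bias-free two-layer
bottleneck (hidden width 4, ReLU then sigmoid) to one multiplicative
weight per stream — 72 trainable scalars in total. Reweighted features
are flattened (9*128 = 1152) into the softmax classifier; three
lightweight per-branch softmax heads provide auxiliary supervision for
the weighted multi-loss.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    DTYPE,
    Adam,
    Conv1d,
    Conv2d,
    Dropout,
    Linear,
    Param,
    relu,
    relu_backward,
    softmax,
)

__all__ = ["FeatureBundle", "MFAModule", "MFACNN", "STREAM_ORDER"]

#: fixed stream order: four EEG bands, the fNIRS block, four cross-modal bands
STREAM_ORDER = (
    "theta",
    "alpha",
    "beta",
    "gamma",
    "fnirs",
    "theta_x",
    "alpha_x",
    "beta_x",
    "gamma_x",
)
N_STREAMS = 9
FEAT_DIM = 128
N_CLASSES = 4
_EEG_SLICE = slice(0, 4)
_FNIRS_SLICE = slice(4, 5)
_XMODAL_SLICE = slice(5, 9)


@dataclass
class FeatureBundle:
    """Per-window model input.

    eeg_gc: [4, n_eeg, n_eeg]; fnirs_ts: [2*n_fnirs, 600];
    xmodal_gc: [4, n_fnirs, n_eeg].
    """

    eeg_gc: np.ndarray
    fnirs_ts: np.ndarray
    xmodal_gc: np.ndarray
    label: int
    clip_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.eeg_gc = np.asarray(self.eeg_gc, dtype=DTYPE)
        self.fnirs_ts = np.asarray(self.fnirs_ts, dtype=DTYPE)
        self.xmodal_gc = np.asarray(self.xmodal_gc, dtype=DTYPE)
        for name in ("eeg_gc", "fnirs_ts", "xmodal_gc"):
            arr = getattr(self, name)
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
        if self.eeg_gc.shape[0] != 4 or self.xmodal_gc.shape[0] != 4:
            raise ValueError("expected one GC matrix per rhythm band")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class MFAModule:
    """Grouped squeeze-and-excitation attention over the 9 streams.

    Three bias-free two-layer bottlenecks (one per modality group) with
    hidden width 4; the sigmoid output may be rescaled by
    `attention_scale` (default 1.0, leaving weights in (0, 1)).
    """

    def __init__(
        self,
        rng: np.random.Generator,
        hidden_width: int = 4,
        attention_scale: float = 1.0,
    ):
        h = hidden_width
        self.hidden_width = h
        self.attention_scale = attention_scale

        def mk(rows: int, cols: int) -> Param:
            return Param(
                rng.uniform(-1, 1, size=(rows, cols)) * np.sqrt(6.0 / (rows + cols))
            )

        # group g: z_g = scale * sigmoid(W_g2 @ relu(W_g1 @ s_g))
        self.w_e1, self.w_e2 = mk(h, 4), mk(4, h)
        self.w_f1, self.w_f2 = mk(h, 1), mk(1, h)
        self.w_c1, self.w_c2 = mk(h, 4), mk(4, h)
        self._cache = None

    def params(self):
        return [
            ("w_e1", self.w_e1),
            ("w_e2", self.w_e2),
            ("w_f1", self.w_f1),
            ("w_f2", self.w_f2),
            ("w_c1", self.w_c1),
            ("w_c2", self.w_c2),
        ]

    def n_parameters(self) -> int:
        return sum(p.size for _, p in self.params())

    def forward(self, s: np.ndarray) -> np.ndarray:
        """Descriptor [B, 9] -> attention weights z [B, 9]."""
        if s.shape[1] != N_STREAMS:
            raise ValueError("descriptor must have 9 entries per sample")
        cache = []
        outs = []
        for sl, w1, w2 in (
            (_EEG_SLICE, self.w_e1, self.w_e2),
            (_FNIRS_SLICE, self.w_f1, self.w_f2),
            (_XMODAL_SLICE, self.w_c1, self.w_c2),
        ):
            sg = s[:, sl]
            pre = sg @ w1.value.T
            hid = relu(pre)
            sig = _sigmoid((hid @ w2.value.T).astype(np.float64)).astype(DTYPE)
            outs.append(self.attention_scale * sig)
            cache.append((sg, pre, hid, sig, w1, w2))
        self._cache = cache
        return np.concatenate(outs, axis=1)

    def backward(self, dz: np.ndarray) -> np.ndarray:
        ds = np.zeros((dz.shape[0], N_STREAMS), dtype=DTYPE)
        for sl, (sg, pre, hid, sig, w1, w2) in zip(
            (_EEG_SLICE, _FNIRS_SLICE, _XMODAL_SLICE), self._cache
        ):
            dsig = dz[:, sl] * self.attention_scale
            dpre2 = dsig * sig * (1.0 - sig)
            w2.grad += dpre2.T @ hid
            dhid = dpre2 @ w2.value
            dpre1 = relu_backward(dhid, pre)
            w1.grad += dpre1.T @ sg
            ds[:, sl] = dpre1 @ w1.value
        return ds


class _Encoder:
    """Conv(32)-ReLU-Conv(64)-ReLU-Conv(128)-ReLU-flatten-FC(128)-dropout."""

    def __init__(
        self,
        kind: str,
        in_ch: int,
        spatial: tuple[int, ...],
        rng: np.random.Generator,
        dropout: float,
    ):
        if kind == "2d":
            h, w = spatial
            if h < 3 or w < 3:
                raise ValueError("2D encoder input must be at least 3x3")
            conv = lambda i, o: Conv2d(i, o, 3, rng)  # noqa: E731
            flat = 128 * h * w
        elif kind == "1d":
            (l,) = spatial
            if l < 3:
                raise ValueError("1D encoder input must have length >= 3")
            conv = lambda i, o: Conv1d(i, o, 3, rng)  # noqa: E731
            flat = 128 * l
        else:
            raise ValueError(kind)
        self.kind = kind
        self.convs = [conv(in_ch, 32), conv(32, 64), conv(64, 128)]
        self.fc = Linear(flat, FEAT_DIM, rng)
        self.drop = Dropout(dropout)
        self._cache = None

    def params(self, prefix: str):
        out = []
        for i, c in enumerate(self.convs):
            out += [(f"{prefix}.conv{i + 1}.{n}", p) for n, p in c.params()]
        out += [(f"{prefix}.fc1.{n}", p) for n, p in self.fc.params()]
        return out

    def forward(self, x: np.ndarray, rng: np.random.Generator, train: bool):
        pres = []
        h = x
        for c in self.convs:
            pre = c.forward(h)
            pres.append(pre)
            h = relu(pre)
        flat = h.reshape(h.shape[0], -1)
        feat = self.fc.forward(flat)
        feat = self.drop.forward(feat, rng, train)
        self._cache = (pres, h.shape)
        return feat

    def backward(self, dfeat: np.ndarray) -> None:
        pres, h_shape = self._cache
        d = self.drop.backward(dfeat)
        d = self.fc.backward(d).reshape(h_shape)
        for c, pre in zip(reversed(self.convs), reversed(pres)):
            d = c.backward(relu_backward(d, pre))


class MFACNN:
    """The full multimodal classifier.

    With use_mfa=False the attention module is absent and the forward
    pass is exactly the plain backbone (equivalent to attention weights
    identically one). Branch heads are always constructed; whether they
    contribute to the loss is the trainer's concern, so backbone
    variants with and without branch supervision share one parameter
    count.
    """

    def __init__(
        self,
        n_eeg_channels: int = 8,
        n_fnirs_channels: int = 4,
        window_len: int = 600,
        use_mfa: bool = True,
        attention_scale: float = 1.0,
        hidden_width: int = 4,
        dropout: float = 0.3,
        seed: int = 0,
    ):
        self.config = dict(
            n_eeg_channels=n_eeg_channels,
            n_fnirs_channels=n_fnirs_channels,
            window_len=window_len,
            use_mfa=use_mfa,
            attention_scale=attention_scale,
            hidden_width=hidden_width,
            dropout=dropout,
            seed=seed,
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D6F64]))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0x64726F70])
        )
        ne, nf = n_eeg_channels, n_fnirs_channels
        self.enc_eeg = _Encoder("2d", 1, (ne, ne), rng, dropout)
        self.enc_fnirs = _Encoder("1d", 2 * nf, (window_len,), rng, dropout)
        self.enc_xmodal = _Encoder("2d", 1, (nf, ne), rng, dropout)
        self.fc2 = Linear(N_STREAMS * FEAT_DIM, N_CLASSES, rng)
        self.head_eeg = Linear(4 * FEAT_DIM, N_CLASSES, rng)
        self.head_fnirs = Linear(FEAT_DIM, N_CLASSES, rng)
        self.head_xmodal = Linear(4 * FEAT_DIM, N_CLASSES, rng)
        # attention parameters are drawn last so backbone weights are
        # bitwise identical across use_mfa settings at a fixed seed
        self.mfa = (
            MFAModule(rng, hidden_width=hidden_width, attention_scale=attention_scale)
            if use_mfa
            else None
        )
        self._cache = None

    # -- parameter bookkeeping ------------------------------------------

    def named_params(self) -> list[tuple[str, Param]]:
        out = []
        out += self.enc_eeg.params("enc_eeg")
        out += self.enc_fnirs.params("enc_fnirs")
        out += self.enc_xmodal.params("enc_xmodal")
        out += [(f"fc2.{n}", p) for n, p in self.fc2.params()]
        out += [(f"head_eeg.{n}", p) for n, p in self.head_eeg.params()]
        out += [(f"head_fnirs.{n}", p) for n, p in self.head_fnirs.params()]
        out += [(f"head_xmodal.{n}", p) for n, p in self.head_xmodal.params()]
        if self.mfa is not None:
            out += [(f"mfa.{n}", p) for n, p in self.mfa.params()]
        return out

    def count_parameters(self, scope: str = "all") -> int:
        """Trainable scalar count for a component scope.

        Scopes: all, mfa, fc2, heads, encoders.
        """
        prefixes = {
            "all": ("",),
            "mfa": ("mfa.",),
            "fc2": ("fc2.",),
            "heads": ("head_eeg.", "head_fnirs.", "head_xmodal."),
            "encoders": ("enc_eeg.", "enc_fnirs.", "enc_xmodal."),
        }
        if scope not in prefixes:
            raise ValueError(f"unknown scope {scope!r}")
        return sum(
            p.size
            for name, p in self.named_params()
            if any(name.startswith(pfx) for pfx in prefixes[scope])
        )

    # -- forward / backward ---------------------------------------------

    @staticmethod
    def batch_from_bundles(bundles) -> dict[str, np.ndarray]:
        return {
            "eeg": np.stack([b.eeg_gc for b in bundles]).astype(DTYPE),
            "fnirs": np.stack([b.fnirs_ts for b in bundles]).astype(DTYPE),
            "xmodal": np.stack([b.xmodal_gc for b in bundles]).astype(DTYPE),
            "labels": np.array([b.label for b in bundles], dtype=np.int64),
        }

    def forward(self, batch: dict[str, np.ndarray], train: bool = False) -> dict:
        eeg, fnirs, xmodal = batch["eeg"], batch["fnirs"], batch["xmodal"]
        b = eeg.shape[0]
        rng = self._dropout_rng
        fe = self.enc_eeg.forward(
            eeg.reshape(b * 4, 1, *eeg.shape[2:]).astype(DTYPE), rng, train
        ).reshape(b, 4, FEAT_DIM)
        ff = self.enc_fnirs.forward(fnirs.astype(DTYPE), rng, train).reshape(
            b, 1, FEAT_DIM
        )
        fx = self.enc_xmodal.forward(
            xmodal.reshape(b * 4, 1, *xmodal.shape[2:]).astype(DTYPE), rng, train
        ).reshape(b, 4, FEAT_DIM)
        x = np.concatenate([fe, ff, fx], axis=1)  # [B, 9, 128]
        s = x.mean(axis=2)  # global average pooling
        if self.mfa is not None:
            z = self.mfa.forward(s)
            x_att = z[:, :, None] * x
        else:
            z = np.ones_like(s)
            x_att = x
        logits = self.fc2.forward(x_att.reshape(b, -1))
        head_logits = {
            "eeg": self.head_eeg.forward(x[:, _EEG_SLICE].reshape(b, -1)),
            "fnirs": self.head_fnirs.forward(x[:, _FNIRS_SLICE].reshape(b, -1)),
            "xmodal": self.head_xmodal.forward(x[:, _XMODAL_SLICE].reshape(b, -1)),
        }
        self._cache = (x, z, b)
        return {
            "logits": logits,
            "head_logits": head_logits,
            "deep_features": x,
            "descriptor": s,
            "attention": z,
        }

    def backward(
        self,
        dlogits: np.ndarray,
        dhead_logits: dict[str, np.ndarray] | None = None,
    ) -> None:
        x, z, b = self._cache
        dx_att = self.fc2.backward(dlogits).reshape(b, N_STREAMS, FEAT_DIM)
        if self.mfa is not None:
            dx = z[:, :, None] * dx_att
            dz = (dx_att * x).sum(axis=2)
            ds = self.mfa.backward(dz.astype(DTYPE))
            dx += ds[:, :, None] / FEAT_DIM
        else:
            dx = dx_att
        if dhead_logits is not None:
            dx[:, _EEG_SLICE] += self.head_eeg.backward(
                dhead_logits["eeg"]
            ).reshape(b, 4, FEAT_DIM)
            dx[:, _FNIRS_SLICE] += self.head_fnirs.backward(
                dhead_logits["fnirs"]
            ).reshape(b, 1, FEAT_DIM)
            dx[:, _XMODAL_SLICE] += self.head_xmodal.backward(
                dhead_logits["xmodal"]
            ).reshape(b, 4, FEAT_DIM)
        self.enc_eeg.backward(dx[:, _EEG_SLICE].reshape(b * 4, FEAT_DIM))
        self.enc_fnirs.backward(dx[:, _FNIRS_SLICE].reshape(b, FEAT_DIM))
        self.enc_xmodal.backward(dx[:, _XMODAL_SLICE].reshape(b * 4, FEAT_DIM))

    def predict_proba(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        return softmax(self.forward(batch, train=False)["logits"].astype(np.float64))

    def make_optimizer(self, lr: float = 0.005) -> Adam:
        return Adam(self.named_params(), lr=lr)

    # -- checkpointing ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {name: p.value for name, p in self.named_params()}
        buf = io.BytesIO()
        np.savez_compressed(buf, **arrays)
        Path(path).write_bytes(
            json.dumps({"config": self.config}).encode() + b"\n" + buf.getvalue()
        )

    @classmethod
    def load(cls, path: str | Path) -> "MFACNN":
        raw = Path(path).read_bytes()
        header, blob = raw.split(b"\n", 1)
        config = json.loads(header)["config"]
        model = cls(**config)
        with np.load(io.BytesIO(blob)) as z:
            for name, p in model.named_params():
                p.value = np.ascontiguousarray(z[name], dtype=DTYPE)
        return model
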