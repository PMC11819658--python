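"""Two-channel semi-supervised GAN anomaly detector for pixel spectra.

One detector is trained per tissue channel (muscle, non-muscle) on clean
spectra only. During training a generator (1-D transposed-conv stack ending
in a sigmoid) synthesises fake spectra and a 1-D U-Net discriminator —
encoder with channel progression 1→2→4→8→16→32 and stride-2 downsampling,
mirrored decoder with skip connections — learns to tell real clean spectra
from generated ones. At inference only the encoder and its sigmoid head
survive: the foreign-material probability of a spectrum is one minus the
encoder's realness score, so anything off the clean-tissue manifold scores
high.

Which spectra belong to which channel is decided by a 1-D Gaussian mixture
on the per-spectrum mean reflectance: lean muscle is darker than fat-rich
connective tissue across the NIR, so the scalar mean separates the two
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from ._nn import (
    Adam,
    Conv1d,
    ConvTranspose1d,
    Dense,
    Param,
    bce_grad,
    bce_with_logits,
    relu,
    relu_backward,
    sigmoid,
)
from .preprocess import SpectrumBatch

REQUIRED_CHANNELS = (2, 4, 8, 16, 32)


# --------------------------------------------------------------------------
# tissue clustering


@dataclass
class GMMParams:
    """Two-component 1-D Gaussian mixture; component 0 has the lower mean."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.means.shape != (2,):
            raise ValueError("exactly two components required")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if self.means[0] > self.means[1]:
            raise ValueError("component 0 must have the lower mean")


def _gmm_feature(batch, band_index: int | None = None) -> np.ndarray:
    m = np.asarray(getattr(batch, "matrix", batch), dtype=float)
    if m.ndim != 2:
        raise ValueError("expected an N x B spectrum batch")
    return m[:, band_index] if band_index is not None else m.mean(axis=1)


def fit_tissue_gmm(
    clean_batch, seed: int = 0, band_index: int | None = None
) -> GMMParams:
    """EM fit of a 2-component mixture on per-spectrum mean reflectance.

    ``band_index`` switches the scalar feature to a single band. Raises on
    degenerate (all-identical) features.
    """
    x = _gmm_feature(clean_batch, band_index)
    if np.ptp(x) == 0:
        raise ValueError("degenerate clustering feature: all values identical")
    gm = GaussianMixture(n_components=2, covariance_type="full", random_state=seed)
    gm.fit(x[:, None])
    means = gm.means_.ravel()
    variances = gm.covariances_.reshape(2)
    weights = gm.weights_.copy()
    order = np.argsort(means, kind="stable")
    return GMMParams(
        means=means[order], variances=variances[order], weights=weights[order]
    )


def assign_cluster(batch, gmm: GMMParams, band_index: int | None = None) -> np.ndarray:
    """Posterior-argmax channel labels in {0, 1}; exact ties go to 0."""
    x = _gmm_feature(batch, band_index)
    log_post = (
        np.log(gmm.weights)[None, :]
        - 0.5 * np.log(2 * np.pi * gmm.variances)[None, :]
        - 0.5 * (x[:, None] - gmm.means[None, :]) ** 2 / gmm.variances[None, :]
    )
    return (log_post[:, 1] > log_post[:, 0]).astype(np.int64)


# --------------------------------------------------------------------------
# architecture


@dataclass
class ArchSpec:
    """Reference discriminator geometry.

    Five conv blocks, kernel 9, stride 2, ReLU; 96→48→24→12→6→3 along the
    spectral axis; head flattens the 3×32 bottleneck through an affine map
    and sigmoid to one realness probability. The decoder mirrors the encoder
    with skip connections and is used only in training.
    """

    input_len: int = 96
    channels: tuple[int, ...] = REQUIRED_CHANNELS
    kernel: int = 9
    stride: int = 2
    latent_dim: int = 16

    def validate(self) -> None:
        if tuple(self.channels) != REQUIRED_CHANNELS:
            raise ValueError(
                f"channel progression must be {REQUIRED_CHANNELS}, got {self.channels}"
            )
        if self.stride != 2:
            raise ValueError("at least one stride-2 block required; reference uses 2")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and positive")
        if self.input_len % 2 ** len(self.channels) != 0:
            raise ValueError("input_len must survive five stride-2 halvings")

    @property
    def bottleneck_len(self) -> int:
        return self.input_len // (self.stride ** len(self.channels))


class _DiscriminatorNet:
    """Encoder + head (inference) and U-Net decoder (training)."""

    def __init__(self, arch: ArchSpec, rng: np.random.Generator):
        arch.validate()
        self.arch = arch
        chans = (1,) + tuple(arch.channels)
        self.enc = [
            Conv1d(chans[i], chans[i + 1], arch.kernel, stride=arch.stride, rng=rng)
            for i in range(len(arch.channels))
        ]
        self.head = Dense(arch.bottleneck_len * arch.channels[-1], 1, rng=rng)
        # decoder input channels double after each skip concatenation
        dec_in = [32, 32, 16, 8, 4]
        dec_out = [16, 8, 4, 2, 1]
        self.dec = [
            ConvTranspose1d(ci, co, arch.kernel, stride=arch.stride, rng=rng)
            for ci, co in zip(dec_in, dec_out)
        ]

    # ---- inference path -------------------------------------------------
    def score(self, x: np.ndarray, fp16: bool = False) -> np.ndarray:
        """Realness probability per spectrum. With ``fp16`` every activation
        is rounded to IEEE binary16 at each layer boundary; accumulation
        inside a layer stays in full precision."""

        def q(a: np.ndarray) -> np.ndarray:
            return a.astype(np.float16).astype(np.float32) if fp16 else a

        a = q(np.asarray(x, dtype=np.float32))
        for conv in self.enc:
            a = q(relu(conv.forward(a)))
        z = q(self.head.forward(a.reshape(a.shape[0], -1)))
        return q(sigmoid(z))[:, 0]

    # ---- training path --------------------------------------------------
    def forward_train(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Head logit (N,1) and per-band decoder logit (N,1,L), with caches."""
        a = np.asarray(x, dtype=np.float32)
        self._e = []
        for conv in self.enc:
            a = relu(conv.forward(a, cache=True))
            self._e.append(a)
        e = self._e
        h = self.head.forward(e[-1].reshape(a.shape[0], -1), cache=True)
        self._u = []
        d = e[-1]
        for i, deconv in enumerate(self.dec[:-1]):
            u = relu(deconv.forward(d, cache=True))
            self._u.append(u)
            d = np.concatenate([u, e[-2 - i]], axis=1)  # skip connection
        dec_logit = self.dec[-1].forward(d, cache=True)
        return h, dec_logit

    def backward(self, ghead: np.ndarray, gdec: np.ndarray) -> np.ndarray:
        """Accumulate parameter grads for both loss branches; return dL/dx."""
        e, u = self._e, self._u
        g_e_extra = [np.zeros_like(ei) for ei in e]  # skip-path gradients
        gflat = self.head.backward(ghead)
        g_e_extra[-1] += gflat.reshape(e[-1].shape)

        g = self.dec[-1].backward(gdec)
        for i in range(len(self.dec) - 2, -1, -1):
            # g is grad wrt concat([u_i, e[-2-i]])
            n_up = u[i].shape[1]
            g_u, g_skip = g[:, :n_up], g[:, n_up:]
            g_e_extra[-2 - i] += g_skip
            g = self.dec[i].backward(relu_backward(g_u, u[i]))
        g_e_extra[-1] += g  # decoder stem starts from the bottleneck

        gx = None
        for i in range(len(self.enc) - 1, -1, -1):
            g_in = g_e_extra[i] if gx is None else gx + g_e_extra[i]
            gx = self.enc[i].backward(relu_backward(g_in, e[i]))
        return gx

    def params(self, inference_only: bool = False) -> list[Param]:
        ps: list[Param] = []
        for layer in self.enc:
            ps += layer.params()
        ps += self.head.params()
        if not inference_only:
            for layer in self.dec:
                ps += layer.params()
        return ps


class _GeneratorNet:
    """Latent noise → 96-band spectrum in (0, 1)."""

    def __init__(self, arch: ArchSpec, rng: np.random.Generator):
        L0 = arch.input_len // 8
        self.L0 = L0
        self.dense = Dense(arch.latent_dim, 8 * L0, rng=rng)
        self.deconvs = [
            ConvTranspose1d(8, 4, arch.kernel, stride=2, rng=rng),
            ConvTranspose1d(4, 2, arch.kernel, stride=2, rng=rng),
            ConvTranspose1d(2, 1, arch.kernel, stride=2, rng=rng),
        ]

    def forward(self, z: np.ndarray, cache: bool = False) -> np.ndarray:
        h = self.dense.forward(z, cache=cache)
        hr = relu(h)
        a = hr.reshape(z.shape[0], 8, self.L0)
        acts = []
        for deconv in self.deconvs[:-1]:
            a = relu(deconv.forward(a, cache=cache))
            acts.append(a)
        logit = self.deconvs[-1].forward(a, cache=cache)
        out = sigmoid(logit)
        if cache:
            self._hr, self._acts, self._out = hr, acts, out
        return out

    def backward(self, gout: np.ndarray) -> None:
        g = gout * self._out * (1.0 - self._out)
        g = self.deconvs[-1].backward(g)
        for deconv, a in zip(reversed(self.deconvs[:-1]), reversed(self._acts)):
            g = deconv.backward(relu_backward(g, a))
        gflat = g.reshape(g.shape[0], -1)
        self.dense.backward(relu_backward(gflat, self._hr))

    def params(self) -> list[Param]:
        ps = self.dense.params()
        for layer in self.deconvs:
            ps += layer.params()
        return ps


@dataclass
class DiscriminatorModel:
    """A trained (or freshly initialised) per-channel discriminator."""

    arch: ArchSpec
    net: _DiscriminatorNet
    precision: str = "fp32"  # "fp32" | "fp16"
    channel_id: str = "muscle"  # "muscle" | "nonmuscle"
    seed: int = 0
    epochs: int = 0

    def parameter_count(self, inference_only: bool = True) -> int:
        return sum(
            p.value.size for p in self.net.params(inference_only=inference_only)
        )

    def mac_count(self) -> int:
        """Multiply-accumulate operations per spectrum, encoder + head."""
        total, L = 0, self.arch.input_len
        for conv in self.net.enc:
            Lout = conv.out_len(L)
            total += Lout * conv.k * conv.c_in * conv.c_out
            L = Lout
        total += self.net.head.w.value.size
        return total

    # ---- persistence -----------------------------------------------------
    def state_dict(self) -> dict:
        layers: dict[str, dict[str, np.ndarray]] = {}
        for i, conv in enumerate(self.net.enc):
            layers[f"enc{i + 1}"] = {"w": conv.w.value, "b": conv.b.value}
        layers["head"] = {"w": self.net.head.w.value, "b": self.net.head.b.value}
        for i, deconv in enumerate(self.net.dec):
            layers[f"dec{i + 1}"] = {"w": deconv.w.value, "b": deconv.b.value}
        return {
            "precision": self.precision,
            "channel_id": self.channel_id,
            "seed": self.seed,
            "epochs": self.epochs,
            "arch": {
                "input_len": self.arch.input_len,
                "channels": np.array(self.arch.channels),
                "kernel": self.arch.kernel,
                "stride": self.arch.stride,
                "latent_dim": self.arch.latent_dim,
            },
            "layers": layers,
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "DiscriminatorModel":
        arch = ArchSpec(
            input_len=int(state["arch"]["input_len"]),
            channels=tuple(int(c) for c in state["arch"]["channels"]),
            kernel=int(state["arch"]["kernel"]),
            stride=int(state["arch"]["stride"]),
            latent_dim=int(state["arch"]["latent_dim"]),
        )
        net = _DiscriminatorNet(arch, np.random.default_rng(0))
        layers = state["layers"]
        pairs = (
            [(f"enc{i + 1}", l) for i, l in enumerate(net.enc)]
            + [("head", net.head)]
            + [(f"dec{i + 1}", l) for i, l in enumerate(net.dec)]
        )
        for name, layer in pairs:
            w, b = layers[name]["w"], layers[name]["b"]
            if w.shape != layer.w.value.shape or b.shape != layer.b.value.shape:
                raise ValueError(f"layer {name}: stored shape does not match arch")
            layer.w.value = np.asarray(w)
            layer.b.value = np.asarray(b)
        return cls(
            arch=arch,
            net=net,
            precision=state["precision"],
            channel_id=state["channel_id"],
            seed=int(state["seed"]),
            epochs=int(state["epochs"]),
        )


def build_discriminator(
    arch: ArchSpec | None = None, seed: int = 0, channel_id: str = "muscle"
) -> DiscriminatorModel:
    """Seeded random initialisation of the reference discriminator."""
    arch = arch or ArchSpec()
    arch.validate()
    net = _DiscriminatorNet(arch, np.random.default_rng(seed))
    return DiscriminatorModel(arch=arch, net=net, channel_id=channel_id, seed=seed)


# --------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Adversarial training hyperparameters (standard small-GAN defaults)."""

    epochs: int = 30
    batch_size: int = 128
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    latent_dim: int = 16
    seed: int = 0
    recon_weight: float = 0.5  # weight of the per-band decoder realness term

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if min(self.batch_size, self.latent_dim) < 1:
            raise ValueError("batch_size and latent_dim must be positive")
        if min(self.lr_g, self.lr_d) <= 0:
            raise ValueError("learning rates must be positive")


class DivergenceError(RuntimeError):
    """Non-finite adversarial loss."""


def train_channel(
    clean_spectra,
    config: TrainConfig | None = None,
    channel_id: str = "muscle",
    arch: ArchSpec | None = None,
) -> DiscriminatorModel:
    """Adversarial training of one tissue channel on clean spectra only.

    Both players minimise non-saturating binary cross-entropy; the decoder
    contributes a per-band realness term with weight ``recon_weight``.
    Deterministic for a fixed (data, seed).
    """
    config = config or TrainConfig()
    config.validate()
    x = np.asarray(getattr(clean_spectra, "matrix", clean_spectra), dtype=np.float32)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("training set must be a non-empty N x B matrix")
    arch = arch or ArchSpec(latent_dim=config.latent_dim)
    if x.shape[1] != arch.input_len:
        raise ValueError(f"spectra have {x.shape[1]} bands, model wants {arch.input_len}")

    model = build_discriminator(arch, seed=config.seed, channel_id=channel_id)
    model.epochs = config.epochs
    if config.epochs == 0:
        return model
    D = model.net
    G = _GeneratorNet(arch, np.random.default_rng((config.seed + 10007) % 2**31))
    rng = np.random.default_rng((config.seed + 20011) % 2**31)

    opt_d = Adam(D.params(), lr=config.lr_d)
    opt_g = Adam(G.params(), lr=config.lr_g)
    w_rec = config.recon_weight
    n = x.shape[0]

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            real = x[idx][:, None, :]
            nb = real.shape[0]
            z = rng.standard_normal((nb, config.latent_dim)).astype(np.float32)
            fake = G.forward(z)  # no caches needed for the D step

            # -- discriminator step: real -> 1, fake -> 0
            opt_d.zero_grad()
            h_r, d_r = D.forward_train(real)
            loss = bce_with_logits(h_r, 1.0) + w_rec * bce_with_logits(d_r, 1.0)
            D.backward(bce_grad(h_r, 1.0), w_rec * bce_grad(d_r, 1.0))
            h_f, d_f = D.forward_train(fake)
            loss += bce_with_logits(h_f, 0.0) + w_rec * bce_with_logits(d_f, 0.0)
            D.backward(bce_grad(h_f, 0.0), w_rec * bce_grad(d_f, 0.0))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"discriminator loss became non-finite ({loss}) at epoch {_epoch}"
                )
            opt_d.step()

            # -- generator step (non-saturating): fool D toward 1
            z2 = rng.standard_normal((nb, config.latent_dim)).astype(np.float32)
            fake2 = G.forward(z2, cache=True)
            h_g, d_g = D.forward_train(fake2)
            g_loss = bce_with_logits(h_g, 1.0) + w_rec * bce_with_logits(d_g, 1.0)
            if not np.isfinite(g_loss):
                raise DivergenceError(
                    f"generator loss became non-finite ({g_loss}) at epoch {_epoch}"
                )
            opt_d.zero_grad()  # D params are frozen for this step
            gx = D.backward(bce_grad(h_g, 1.0), w_rec * bce_grad(d_g, 1.0))
            opt_g.zero_grad()
            G.backward(gx)
            opt_g.step()
            opt_d.zero_grad()

    return model


def score_spectra(model: DiscriminatorModel, batch) -> np.ndarray:
    """Per-spectrum foreign-material probability (1 − encoder realness).

    Scores are independent per pixel, so scoring a batch whole or as a
    concatenation of sub-batches is bitwise identical. An fp16 model is
    evaluated with half-precision activation rounding at layer boundaries.
    """
    m = np.asarray(getattr(batch, "matrix", batch), dtype=np.float32)
    if m.ndim != 2 or m.shape[1] != model.arch.input_len:
        raise ValueError(
            f"expected N x {model.arch.input_len} spectra, got {m.shape}"
        )
    realness = model.net.score(m[:, None, :], fp16=(model.precision == "fp16"))
    return 1.0 - realness
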