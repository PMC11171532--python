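"""Registration network: U-Net displacement prediction + spatial transformer.

The network takes the fixed image and the horizontally flipped moving
image stacked as two channels and predicts a dense displacement field
(one 2-vector per pixel, in pixels of the fixed frame).  The flipped
image is then resampled at ``grid + field`` with bilinear interpolation
to produce the transformed image.  Architecture follows the original
unsupervised deformable-registration U-Net: stride-2 convolutional
encoder, nearest-neighbour-upsampling decoder with skip connections,
LeakyReLU(0.2) activations, and a final flow convolution initialised at
zero so the untrained model is the identity transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad

__all__ = [
    "UNetConfig",
    "RegistrationUNet",
    "predict_displacement",
    "warp_image",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class UNetConfig:
    """Channel plan for the registration U-Net.

    ``encoder_channels`` lists the output channels of the stride-2
    encoder convolutions; ``decoder_channels`` must have three more
    entries than the encoder (the skip-connected decoder convolutions,
    one extra half-resolution convolution, and two full-resolution
    refinement convolutions before the flow layer).
    """

    encoder_channels: tuple = (16, 32, 32, 32)
    decoder_channels: tuple = (32, 32, 32, 32, 32, 16, 16)
    in_channels: int = 2
    leaky_slope: float = 0.2

    def __post_init__(self):
        if len(self.decoder_channels) != len(self.encoder_channels) + 3:
            raise ValueError(
                "decoder_channels must have len(encoder_channels) + 3 entries"
            )


#: Half-width channel plan used for desk-scale experiments at 128x128.
SMALL_CONFIG = UNetConfig(
    encoder_channels=(8, 16, 16, 16),
    decoder_channels=(16, 16, 16, 16, 16, 8, 8),
)


class _Conv:
    def __init__(self, rng, c_in, c_out, stride=1, zero_init=False):
        if zero_init:
            w = np.zeros((c_out, c_in, 3, 3), dtype=np.float32)
        else:
            std = np.sqrt(2.0 / (c_in * 9))
            w = rng.normal(0.0, std, (c_out, c_in, 3, 3)).astype(np.float32)
        self.w = ad.Tensor(w, requires_grad=True)
        self.b = ad.Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride = stride

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b, stride=self.stride, pad=1)


class RegistrationUNet:
    """U-Net mapping a (fixed, flipped) pair to a dense displacement field."""

    def __init__(self, config: UNetConfig = UNetConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        enc, dec = config.encoder_channels, config.decoder_channels
        self.enc_convs = []
        c = config.in_channels
        for ch in enc:
            self.enc_convs.append(_Conv(rng, c, ch, stride=2))
            c = ch
        n_skip = len(enc)
        self.dec_convs = []
        # skip-connected stage: first conv sees the deepest encoder output
        for i in range(n_skip):
            c_in = c if i == 0 else dec[i - 1] + enc[n_skip - 1 - i]
            self.dec_convs.append(_Conv(rng, c_in, dec[i]))
        # extra half-resolution conv, then two full-resolution convs
        self.dec_convs.append(_Conv(rng, dec[n_skip - 1], dec[n_skip]))
        self.dec_convs.append(
            _Conv(rng, dec[n_skip] + config.in_channels, dec[n_skip + 1])
        )
        self.dec_convs.append(_Conv(rng, dec[n_skip + 1], dec[n_skip + 2]))
        self.flow = _Conv(rng, dec[-1], 2, zero_init=True)

    def parameters(self):
        ps = []
        for conv in self.enc_convs + self.dec_convs + [self.flow]:
            ps.extend([conv.w, conv.b])
        return ps

    def forward(self, fixed_moving: ad.Tensor) -> ad.Tensor:
        """``fixed_moving`` is (N, 2, H, W); returns the (N, 2, H, W) field."""
        a = self.config.leaky_slope
        h, w = fixed_moving.data.shape[2:]
        f = 2 ** len(self.enc_convs)
        if h % f or w % f:
            raise ValueError(f"input size {h}x{w} not divisible by {f}")
        skips = [fixed_moving]
        x = fixed_moving
        for conv in self.enc_convs:
            x = ad.leaky_relu(conv(x), a)
            skips.append(x)
        n_skip = len(self.enc_convs)
        x = ad.leaky_relu(self.dec_convs[0](x), a)
        for i in range(1, n_skip):
            x = ad.upsample_nearest(x)
            x = ad.concat_channels([x, skips[n_skip - i]])
            x = ad.leaky_relu(self.dec_convs[i](x), a)
        x = ad.leaky_relu(self.dec_convs[n_skip](x), a)
        x = ad.upsample_nearest(x)
        x = ad.concat_channels([x, skips[0]])
        x = ad.leaky_relu(self.dec_convs[n_skip + 1](x), a)
        x = ad.leaky_relu(self.dec_convs[n_skip + 2](x), a)
        return self.flow(x)


def _as_batch(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return img[None, None]


def predict_displacement(
    model: RegistrationUNet, fixed: np.ndarray, flipped: np.ndarray
) -> np.ndarray:
    """Predict the displacement field for one preprocessed pair.

    Returns a ``(2, H, W)`` float32 array: channel 0 is the row
    displacement, channel 1 the column displacement, in pixels.
    """
    f, m = _as_batch(fixed), _as_batch(flipped)
    if f.shape != m.shape:
        raise ValueError(f"shape mismatch: fixed {f.shape[2:]} vs flipped {m.shape[2:]}")
    x = ad.Tensor(np.concatenate([f, m], axis=1))
    return model.forward(x).data[0]


def warp_image(moving: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Resample ``moving`` at ``grid + field`` with bilinear interpolation.

    Out-of-bounds positions clamp to the image border, so warped
    intensities always stay within the input's range.
    """
    m = _as_batch(moving)
    field = np.asarray(field, dtype=np.float32)
    if field.shape != (2,) + m.shape[2:]:
        raise ValueError(
            f"field shape {field.shape} does not match image {m.shape[2:]}"
        )
    out = ad.warp_bilinear(ad.Tensor(m), ad.Tensor(field[None]))
    return out.data[0, 0]


def save_weights(model: RegistrationUNet, path) -> None:
    """Write weights (.npz) plus a JSON sidecar describing the channel plan."""
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "encoder_channels": list(model.config.encoder_channels),
                "decoder_channels": list(model.config.decoder_channels),
                "in_channels": model.config.in_channels,
                "leaky_slope": model.config.leaky_slope,
            }
        )
    )


def load_weights(path) -> RegistrationUNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    cfg = json.loads(path.with_suffix(".json").read_text())
    model = RegistrationUNet(
        UNetConfig(
            encoder_channels=tuple(cfg["encoder_channels"]),
            decoder_channels=tuple(cfg["decoder_channels"]),
            in_channels=cfg["in_channels"],
            leaky_slope=cfg["leaky_slope"],
        )
    )
    with np.load(path) as data:
        for i, p in enumerate(model.parameters()):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("weights file does not match configuration")
            p.data = arr.astype(np.float32)
    return model
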