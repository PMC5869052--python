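"""Composable network blocks with hierarchical named scopes.

Every trainable parameter lives in a flat ``scope/path/name`` registry owned
by its :class:`Module`; blocks are plain functions that create (or, when the
scope already exists, *reuse*) their parameters, so invoking a block twice
under one name shares weights without breaking encapsulation.  A
:class:`LayerHandle` is a view of one scope subtree — the unit that
checkpoint restore can transplant between networks.

Feature maps are ``(batch, channels, x, y, z)`` float32 tensors.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, Variable


class NetworkError(RuntimeError):
    pass


class Module:
    """Base class owning a scoped parameter registry.

    Subclasses implement ``forward``; parameters are created lazily on the
    first forward pass (initialized from ``init_rng``) and reused on every
    later call.
    """

    def __init__(self, name: str = "net", init_rng: np.random.Generator | None = None):
        self.name = name
        self.params: dict[str, Variable] = {}
        self._scope: list[str] = [name]
        self.init_rng = init_rng or np.random.default_rng(0)

    # -- scopes --------------------------------------------------------------

    @contextmanager
    def scoped(self, name: str):
        self._scope.append(name)
        try:
            yield
        finally:
            self._scope.pop()

    def scope_path(self, name: str | None = None) -> str:
        parts = self._scope + ([name] if name else [])
        return "/".join(parts)

    def param(self, name: str, shape: tuple, init) -> Variable:
        """Create-or-reuse a parameter under the current scope."""
        full = self.scope_path(name)
        if full in self.params:
            var = self.params[full]
            if var.data.shape != tuple(shape):
                raise NetworkError(
                    f"scope {full!r} reused with shape {tuple(shape)}, "
                    f"existing {var.data.shape}"
                )
            return var
        if callable(init):
            data = init(shape, self.init_rng)
        else:
            data = np.broadcast_to(np.asarray(init, dtype=ad.DTYPE), shape).copy()
        var = Variable(data)
        self.params[full] = var
        return var

    def variables(self) -> list[Variable]:
        return list(self.params.values())

    def handle(self, scope: str | None = None) -> "LayerHandle":
        return LayerHandle(self, scope or self.name)

    def zero_grad(self) -> None:
        for v in self.params.values():
            v.zero_grad()

    def build(self, input_shape: tuple) -> None:
        """Materialize all parameters with a zero forward pass."""
        self.forward(Tensor(np.zeros(input_shape, dtype=ad.DTYPE)))

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class LayerHandle:
    """A named view of one scope subtree of a module's parameters."""

    module: Module
    scope: str

    @property
    def parameters(self) -> dict[str, Variable]:
        prefix = self.scope + "/"
        return {
            k: v for k, v in self.module.params.items()
            if k == self.scope or k.startswith(prefix)
        }

    @property
    def child_layers(self) -> list[str]:
        prefix = self.scope + "/"
        children = {
            k[len(prefix):].split("/")[0]
            for k in self.module.params if k.startswith(prefix)
        }
        return sorted(children)


def he_init(shape, rng: np.random.Generator) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else int(shape[0])
    std = np.sqrt(2.0 / max(fan_in, 1))
    return (rng.standard_normal(shape) * std).astype(ad.DTYPE)


_ACTIVATIONS = {
    "relu": ad.relu,
    "leaky_relu": ad.leaky_relu,
    "sigmoid": ad.sigmoid,
    "tanh": ad.tanh,
    "linear": lambda t: t,
    None: lambda t: t,
}


def conv_block(
    module: Module,
    x: Tensor,
    out_channels: int,
    kernel: int = 3,
    activation: str | None = "relu",
    name: str = "conv",
    normalize: bool = True,
) -> Tensor:
    """Convolution (stride 1, same padding) → instance norm → activation.

    The normalization is batch-independent (statistics per sample and
    channel over the spatial axes), so tiny batches behave identically to
    large ones.
    """
    in_channels = x.shape[1]
    with module.scoped(name):
        w = module.param("w", (out_channels, in_channels, kernel, kernel, kernel), he_init)
        b = module.param("b", (out_channels,), 0.0)
        y = ad.conv3d(x, w, b)
        if normalize:
            gamma = module.param("gamma", (1, out_channels, 1, 1, 1), 1.0)
            beta = module.param("beta", (1, out_channels, 1, 1, 1), 0.0)
            y = ad.instance_norm(y, gamma, beta)
    try:
        act = _ACTIVATIONS[activation]
    except KeyError:
        raise NetworkError(f"unknown activation {activation!r}") from None
    return act(y)


def dense_feature_stack(
    module: Module,
    x: Tensor,
    n_blocks: int,
    growth_channels: int,
    kernel: int = 3,
    name: str = "dfs",
) -> Tensor:
    """A dense stack: block *i* consumes the concatenation of the stack
    input and the outputs of blocks 1..i-1; the stack returns the
    concatenation of all block outputs (``n_blocks * growth_channels``
    channels)."""
    if n_blocks < 1:
        raise NetworkError("dense_feature_stack needs n_blocks >= 1")
    outputs: list[Tensor] = []
    with module.scoped(name):
        for i in range(n_blocks):
            inp = x if not outputs else ad.concat([x] + outputs, axis=1)
            outputs.append(
                conv_block(module, inp, growth_channels, kernel=kernel,
                           name=f"block{i + 1}")
            )
    return outputs[0] if n_blocks == 1 else ad.concat(outputs, axis=1)


class ReferenceSegNet(Module):
    """A small V-shaped segmentation network.

    Each level applies a dense feature stack then 2x average-pool
    downsampling; the upward path uses trilinear 2x upsampling, and each
    skip connection is a 3^3 convolution of the level's stack output summed
    into the upsampled features; a final 1^3 convolution produces one score
    channel per class.  Depth 2 with growth 8 gives a ~50k-parameter model
    that trains on a CPU in minutes.
    """

    def __init__(
        self,
        in_channels: int,
        n_classes: int,
        depth: int = 2,
        growth: int = 8,
        blocks_per_level: int = 2,
        skip_channels: int = 8,
        name: str = "segnet",
        init_rng=None,
    ):
        super().__init__(name=name, init_rng=init_rng)
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.depth = depth
        self.growth = growth
        self.blocks_per_level = blocks_per_level
        self.skip_channels = skip_channels

    def forward(self, x: Tensor) -> Tensor:
        spatial = x.shape[2:]
        if any(d % (2 ** self.depth) for d in spatial):
            raise NetworkError(
                f"spatial shape {spatial} not divisible by 2^{self.depth}"
            )
        skips: list[Tensor] = []
        h = x
        for level in range(self.depth):
            with self.scoped(f"level{level}"):
                feats = dense_feature_stack(
                    self, h, self.blocks_per_level, self.growth
                )
                skips.append(
                    conv_block(self, feats, self.skip_channels, name="skip")
                )
                h = ad.avg_pool2(feats)
        with self.scoped("bottom"):
            h = conv_block(self, h, self.skip_channels, name="conv")
        for level in reversed(range(self.depth)):
            with self.scoped(f"up{level}"):
                h = ad.upsample2_linear(h)
                h = h + skips[level]
                h = conv_block(self, h, self.skip_channels, name="refine")
        with self.scoped("classifier"):
            # the raw input joins the final features: every normalization in
            # the trunk is window-relative, so this is the only path that
            # carries absolute (volume-standardized) intensity to the scores
            scores = conv_block(
                self, ad.concat([h, x], axis=1), self.n_classes, kernel=1,
                activation=None, normalize=False, name="final",
            )
        return scores


class ReferenceRegressionNet(ReferenceSegNet):
    """The same V-shaped trunk with a single continuous output channel."""

    def __init__(self, in_channels: int, n_out: int = 1, name: str = "regnet", **kw):
        super().__init__(in_channels, n_classes=n_out, name=name, **kw)


class IdentityNet(Module):
    """Parameterless network returning its input unchanged.

    Used to exercise the sample → forward → aggregate round trip, whose
    correctness is independent of any trained model.
    """

    def __init__(self, name: str = "identity", init_rng=None):
        super().__init__(name=name, init_rng=init_rng)

    def forward(self, x: Tensor) -> Tensor:
        return x


class MLP(Module):
    """A small fully connected network on (batch, features) inputs; the
    building block for the toy GAN generator/discriminator pair."""

    def __init__(self, sizes, activation="leaky_relu", final_activation=None,
                 name: str = "mlp", init_rng=None):
        super().__init__(name=name, init_rng=init_rng)
        self.sizes = list(sizes)
        self.activation = activation
        self.final_activation = final_activation

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for i, (nin, nout) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            with self.scoped(f"fc{i + 1}"):
                w = self.param("w", (nin, nout), he_init)
                b = self.param("b", (nout,), 0.0)
            h = ad.matmul(h, w) + b
            last = i == len(self.sizes) - 2
            act = self.final_activation if last else self.activation
            h = _ACTIVATIONS[act](h)
        return h


def build_reference_segnet(
    in_channels: int, n_classes: int, config: dict | None = None
) -> ReferenceSegNet:
    """Convenience constructor for the reference V-shaped segmentation net."""
    cfg = dict(config or {})
    return ReferenceSegNet(in_channels, n_classes, **cfg)


# -- network factory ---------------------------------------------------------

_BUILTIN_NETWORKS = {
    "segnet": ReferenceSegNet,
    "regression": ReferenceRegressionNet,
    "identity": IdentityNet,
}


def resolve_network(name: str):
    """Map a config network name to a factory.

    Built-in names are looked up directly; anything containing a dot (or a
    ``module:attr`` form) is imported as a plugin by Python import path.
    """
    if name in _BUILTIN_NETWORKS:
        return _BUILTIN_NETWORKS[name]
    import importlib

    mod_name, _, attr = name.replace(":", ".").rpartition(".")
    if not mod_name:
        raise NetworkError(f"unknown network {name!r}")
    try:
        mod = importlib.import_module(mod_name)
        return getattr(mod, attr)
    except (ImportError, AttributeError) as exc:
        raise NetworkError(f"cannot resolve network plugin {name!r}: {exc}") from exc
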