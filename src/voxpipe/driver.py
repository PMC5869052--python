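"""The application driver: configuration in, trained/inferred/evaluated
results out.

One master seed drives everything through *named* RNG streams: each
component (sampler, augmentation, noise, init) draws from its own stream,
and training streams are re-derived per step, so a run resumed from a
checkpoint at step *k* consumes exactly the random numbers an uninterrupted
run would have consumed.  Checkpoints embed the fully resolved
configuration, making them self-sufficient for inference.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as eval_mod
from .aggregation import (
    accumulate_window,
    finalize_aggregation,
    init_grid_aggregation,
    resize_aggregate,
)
from .config import ConfigError, ConfigSpec, parse_config
from .nn import (
    Adam,
    Tensor,
    load_checkpoint,
    resolve_network,
    restore_checkpoint,
    rmse_loss,
    save_checkpoint,
    soft_dice_loss,
    softmax,
)
from .phantoms import generate_conditioning_map
from .preprocessing import (
    AugmentationParams,
    apply_transform,
    meanvar_normalize,
    sample_affine,
)
from .sampling import (
    SampleWindow,
    grid_sample,
    resize_sample,
    sample_noise,
    uniform_sample,
    weighted_sample,
)
from .volume_io import (
    DatasetIndex,
    ImageVolume,
    SectionSpec,
    discover_dataset,
    load_manifest,
    load_volume,
    write_volume,
)

logger = logging.getLogger(__name__)

OUTPUT_SUFFIX = "_niftynet_out.nii.gz"


class DriverError(RuntimeError):
    pass


def stream_rng(seed: int, name: str, step: int | None = None) -> np.random.Generator:
    """A named child RNG stream of the master seed.

    Streams are independent per (seed, name[, step]); deriving training
    streams per step makes checkpoint resumption exact.
    """
    entropy = [int(seed), zlib.crc32(name.encode())]
    if step is not None:
        entropy.append(int(step))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class RunLog:
    """Per-iteration loss records plus file/console sinks."""

    records: list[tuple[int, float, float]] = field(default_factory=list)
    path: Path | None = None

    def log(self, step: int, loss: float) -> None:
        if self.records and step <= self.records[-1][0]:
            raise DriverError(f"non-monotone step {step}")
        stamp = time.time()
        self.records.append((step, float(loss), stamp))
        line = f"step {step:6d}  loss {loss:.6f}"
        logger.info(line)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(f"{stamp:.3f} {line}\n")

    @property
    def losses(self) -> list[float]:
        return [r[1] for r in self.records]


# ---------------------------------------------------------------------------
# dataset plumbing
# ---------------------------------------------------------------------------

def build_index(config: ConfigSpec) -> DatasetIndex:
    """Assemble the subject table from the config's data sections."""
    per_section: dict[str, dict[str, Path]] = {}
    order_source: list[str] | None = None
    for name, entry in config.data.items():
        if entry["csv_file"]:
            manifest = load_manifest(entry["csv_file"])
            if name not in manifest.section_names:
                raise DriverError(
                    f"manifest {entry['csv_file']} has no column {name!r}"
                )
            per_section[name] = {
                sid: manifest.subjects[sid][name] for sid in manifest.subject_ids
            }
        else:
            found = discover_dataset(
                entry["path_to_search"], {name: [entry["filename_contains"]]}
            )
            per_section[name] = {
                sid: found.subjects[sid][name] for sid in found.subject_ids
            }
        if order_source is None:
            order_source = list(per_section[name])

    common = [
        sid for sid in (order_source or [])
        if all(sid in paths for paths in per_section.values())
    ]
    for name, entry in config.data.items():
        wanted = entry["subjects"].split()
        if wanted:
            common = [sid for sid in common if sid in wanted]
    if not common:
        raise DriverError("no subjects present in every data section")
    subjects = {sid: {sec: per_section[sec][sid] for sec in per_section} for sid in common}
    index = DatasetIndex(subjects=subjects)
    for name, entry in config.data.items():
        if entry["interp_order"] >= 0:
            index.section_specs[name] = SectionSpec(name, entry["interp_order"])
    return index


def load_subject(
    index: DatasetIndex, sid: str, normalization: str = "meanvar"
) -> dict[str, ImageVolume]:
    """Load (and intensity-normalize) every section of one subject."""
    vols: dict[str, ImageVolume] = {}
    for section, path in index.subjects[sid].items():
        vol = load_volume(path, index.section_specs.get(section))
        vol = ImageVolume(vol.data, vol.affine, section=section,
                          modality_names=list(vol.modality_names))
        if section == "image" and normalization == "meanvar":
            vol = meanvar_normalize(vol)
        vols[section] = vol
    return vols


def _window_to_batch(windows: list[SampleWindow], section: str) -> np.ndarray:
    """Stack window arrays into a (N, C, X, Y, Z) float32 batch."""
    batch = []
    for w in windows:
        arr = w.arrays[section]
        arr = arr.reshape(arr.shape[:3] + (-1,))  # merge time into channels
        batch.append(np.moveaxis(arr, 3, 0))
    return np.asarray(np.stack(batch), dtype=np.float32)


def _window_labels(windows: list[SampleWindow], section: str = "label") -> np.ndarray:
    return np.stack([
        np.squeeze(np.asarray(w.arrays[section])).astype(np.int64) for w in windows
    ])


def make_network(config: ConfigSpec, in_channels: int, init_rng=None):
    """Instantiate the configured network (built-in name or plugin path)."""
    name = config.network["name"]
    factory = resolve_network(name)
    if name == "identity" or getattr(factory, "__name__", "") == "IdentityNet":
        return factory(init_rng=init_rng)
    kwargs = dict(
        depth=config.network["depth"],
        growth=config.network["growth"],
        blocks_per_level=config.network["blocks_per_level"],
        skip_channels=config.network["skip_channels"],
        init_rng=init_rng,
    )
    if name == "regression":
        return factory(in_channels, n_out=1, **kwargs)
    try:
        return factory(in_channels, config.network["n_classes"], **kwargs)
    except TypeError:
        # external plugins choose their own signature
        return factory(in_channels, config.network["n_classes"])


def _latest_checkpoint(model_dir: Path) -> Path:
    ckpt_dir = model_dir / "checkpoints"
    candidates = sorted(ckpt_dir.glob("step_*")) if ckpt_dir.is_dir() else []
    if not candidates:
        raise DriverError(f"no checkpoint found under {ckpt_dir}")
    return candidates[-1]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def run_training(config: ConfigSpec) -> tuple[RunLog, Path]:
    """The training loop: sample → augment → forward → loss → update.

    Checkpoints (parameters, optimizer state and the resolved config) are
    written every ``save_every`` steps and at the end; a non-finite loss
    aborts with the offending step in the message.
    """
    seed = config.seed
    model_dir = config.model_dir
    (model_dir / "logs").mkdir(parents=True, exist_ok=True)
    (model_dir / "checkpoints").mkdir(parents=True, exist_ok=True)
    run_log = RunLog(path=model_dir / "logs" / "run.log")

    index = build_index(config)
    tr = config.training
    window = tuple(tr["spatial_window_size"])
    subjects = {
        sid: load_subject(index, sid, tr["normalization"])
        for sid in index.subject_ids
    }
    first = subjects[index.subject_ids[0]]
    in_channels = first["image"].n_channels * first["image"].data.shape[3]

    net = make_network(config, in_channels, init_rng=stream_rng(seed, "init"))
    net.build((1, in_channels) + window)
    optimizer = Adam(net.variables(), lr=tr["lr"])

    start_step = 0
    if tr["starting_checkpoint"]:
        ckpt = Path(tr["starting_checkpoint"])
        start_step = restore_checkpoint(ckpt, net)
        _restore_optimizer(optimizer, ckpt)

    aug_params = AugmentationParams(
        flip_axes=tuple(tr["flip_axes"]),
        rotation_range_deg=tuple(tr["rotation_range_deg"]),
        scaling_range_pct=tuple(tr["scaling_range_pct"]),
    ) if tr["augmentation"] else None

    loss_name = tr["loss"]
    n_classes = config.network["n_classes"]
    config_text = config.resolved_text()
    last_ckpt = None

    for step in range(start_step, tr["iterations"]):
        rng_samp = stream_rng(seed, "sampler", step)
        sid = index.subject_ids[int(rng_samp.integers(len(index)))]
        vols = subjects[sid]
        if aug_params is not None:
            rng_aug = stream_rng(seed, "augmentation", step)
            transform = sample_affine(aug_params, rng_aug)
            names = list(vols)
            vols = dict(zip(names, apply_transform([vols[n] for n in names], transform)))

        if tr["sampler"] == "weighted":
            windows = list(weighted_sample(vols, window, "weight",
                                           tr["batch_size"], rng_samp, sid))
        elif tr["sampler"] == "resize":
            windows = [resize_sample(vols, window, sid)] * tr["batch_size"]
        else:
            windows = list(uniform_sample(vols, window, tr["batch_size"],
                                          rng_samp, sid))

        x = Tensor(_window_to_batch(windows, "image"))
        net.zero_grad()
        scores = net.forward(x)
        if loss_name == "dice":
            labels = _window_labels(windows)
            loss = soft_dice_loss(softmax(scores, axis=1), labels, n_classes)
        elif loss_name == "rmse":
            target = _window_to_batch(windows, "target")
            loss = rmse_loss(scores, target)
        else:
            raise DriverError(f"unknown loss {loss_name!r}")
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise DriverError(f"non-finite loss ({loss_val}) at step {step}")
        loss.backward()
        optimizer.step()
        run_log.log(step, loss_val)

        if (step + 1) % tr["save_every"] == 0 or step + 1 == tr["iterations"]:
            last_ckpt = model_dir / "checkpoints" / f"step_{step + 1:06d}"
            save_checkpoint(net, step + 1, config_text, last_ckpt)
            _save_optimizer(optimizer, last_ckpt)

    if last_ckpt is None:
        last_ckpt = model_dir / "checkpoints" / f"step_{tr['iterations']:06d}"
        save_checkpoint(net, tr["iterations"], config_text, last_ckpt)
        _save_optimizer(optimizer, last_ckpt)
    return run_log, last_ckpt


def _save_optimizer(optimizer: Adam, directory: Path) -> None:
    arrays = {}
    for i, (m, v) in enumerate(zip(optimizer._m, optimizer._v)):
        arrays[f"m{i}"] = m
        arrays[f"v{i}"] = v
    np.savez(directory / "optim.npz", t=np.array(optimizer.t), **arrays)


def _restore_optimizer(optimizer: Adam, directory: Path) -> None:
    path = directory / "optim.npz"
    if not path.exists():
        return
    with np.load(path) as data:
        optimizer.t = int(data["t"])
        for i in range(len(optimizer.variables)):
            if f"m{i}" in data:
                optimizer._m[i] = data[f"m{i}"].copy()
                optimizer._v[i] = data[f"v{i}"].copy()


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def run_inference(config: ConfigSpec, checkpoint: str | Path | None = None) -> list[Path]:
    """Systematic sampling → forward → aggregation → NIfTI outputs.

    Deterministic given the checkpoint: the same call produces bitwise
    identical output volumes.
    """
    inf = config.inference
    index = build_index(config)
    out_dir = Path(inf["output_dir"]) if inf["output_dir"] else config.model_dir / "output"
    out_dir.mkdir(parents=True, exist_ok=True)
    window = tuple(inf["spatial_window_size"])
    border = tuple(inf["border"])

    first = load_subject(index, index.subject_ids[0], inf["normalization"])
    in_channels = first["image"].n_channels * first["image"].data.shape[3]
    net = make_network(config, in_channels, init_rng=stream_rng(config.seed, "init"))
    net.build((1, in_channels) + window)
    if net.params:
        ckpt = Path(checkpoint) if checkpoint else (
            Path(inf["checkpoint"]) if inf["checkpoint"]
            else _latest_checkpoint(config.model_dir)
        )
        restore_checkpoint(ckpt, net)

    output_kind = inf["output_kind"]
    written: list[Path] = []
    for sid in index.subject_ids:
        vols = {"image": load_subject(index, sid, inf["normalization"])["image"]}
        reference = vols["image"]

        def forward_window(w: SampleWindow) -> np.ndarray:
            x = Tensor(_window_to_batch([w], "image"))
            scores = net.forward(x)
            if output_kind == "label":
                scores = softmax(scores, axis=1)
            return np.moveaxis(scores.data[0], 0, 3)  # (x, y, z, c)

        if inf["sampler"] == "resize":
            w = resize_sample(vols, window, sid)
            out = forward_window(w)
            vol = resize_aggregate(w, out, output_kind, reference=reference)
        elif inf["sampler"] == "grid":
            windows = grid_sample(vols, window, border, sid)
            out0 = forward_window(windows[0])
            state = init_grid_aggregation(
                windows[0].original_shape, out0.shape[3], border,
                padding_offset=windows[0].padding_offset,
            )
            accumulate_window(state, windows[0], out0)
            for w in windows[1:]:
                accumulate_window(state, w, forward_window(w))
            if inf["save_probabilities"] and output_kind == "label":
                probs = state.output / state.weight[..., np.newaxis]
                prob_vol = ImageVolume(probs.astype(np.float32), reference.affine,
                                       section="inferred",
                                       modality_names=[f"class{i}" for i in range(probs.shape[3])])
                write_volume(prob_vol, out_dir / f"{sid}_niftynet_prob.nii.gz", reference)
            vol = finalize_aggregation(state, output_kind, reference=reference)
        else:
            raise DriverError(f"inference sampler must be grid or resize, got {inf['sampler']!r}")

        path = out_dir / f"{sid}{OUTPUT_SUFFIX}"
        write_volume(vol, path, reference)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def run_evaluation(config: ConfigSpec) -> pd.DataFrame:
    """Delegate to the evaluation suite; CSV lands in the model directory."""
    ev = config.evaluation
    index = build_index(config)
    seg_dir = Path(ev["seg_dir"]) if ev["seg_dir"] else (
        Path(config.inference["output_dir"]) if config.inference["output_dir"]
        else config.model_dir / "output"
    )
    metrics = tuple(ev["metrics"].split()) if ev["metrics"] else eval_mod.DEFAULT_METRICS
    labels = [int(x) for x in ev["labels"].split()] if ev["labels"] else None
    csv_path = config.model_dir / "evaluation.csv"
    config.model_dir.mkdir(parents=True, exist_ok=True)
    return eval_mod.evaluate_subjects(
        index, seg_dir, metrics=metrics, labels=labels,
        distance_units=ev["distance_units"], csv_path=csv_path,
    )


# ---------------------------------------------------------------------------
# linear-interpolation inference for generative models
# ---------------------------------------------------------------------------

def linear_interpolation_inference(
    generator,
    conditioning: ImageVolume | np.ndarray | None,
    n_steps: int,
    rng: np.random.Generator,
    noise_dim: int = 100,
    checkpoint: str | Path | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Generate images along a straight line in latent space.

    Draws two latent vectors z1, z2 and evaluates the generator at
    ``z_i = z1 + (i-1)/(n_steps-1) (z2 - z1)`` with the *same* conditioning
    image for every step.  Returns (latents, images).
    """
    if n_steps < 2:
        raise DriverError(f"n_steps must be >= 2, got {n_steps}")
    if checkpoint is not None:
        restore_checkpoint(checkpoint, generator)
    z1, z2 = (s.vector for s in sample_noise(noise_dim, 2, rng))
    cond_flat = None
    if conditioning is not None:
        cond = conditioning.data if isinstance(conditioning, ImageVolume) else np.asarray(conditioning)
        cond_flat = cond.astype(np.float32).ravel()

    latents, images = [], []
    for i in range(n_steps):
        t = i / (n_steps - 1)
        z = z1 + t * (z2 - z1)
        latents.append(z)
        vec = z if cond_flat is None else np.concatenate([z, cond_flat])
        out = generator.forward(Tensor(vec[np.newaxis, :].astype(np.float32)))
        images.append(out.data[0].copy())
    return latents, images


# ---------------------------------------------------------------------------
# entry point used by the CLI
# ---------------------------------------------------------------------------

def run_linear_interpolation(config: ConfigSpec) -> list[Path]:
    """The linear_interpolation action: load a generator plugin, sweep the
    latent line between two noise draws (same conditioning throughout) and
    write one volume per step."""
    inf = config.inference
    factory = resolve_network(config.network["name"])
    generator = factory()
    conditioning = None
    if inf["conditioning_shape"]:
        conditioning = generate_conditioning_map(inf["conditioning_shape"])
    ckpt = Path(inf["checkpoint"]) if inf["checkpoint"] else _latest_checkpoint(config.model_dir)
    rng = stream_rng(config.seed, "noise")
    # materialize parameters before restore
    probe = rng.standard_normal(inf["noise_dim"])
    if conditioning is not None:
        probe = np.concatenate([probe, conditioning.data.ravel()])
    generator.build((1, probe.size))
    _, images = linear_interpolation_inference(
        generator, conditioning, inf["n_steps"],
        stream_rng(config.seed, "noise"), noise_dim=inf["noise_dim"],
        checkpoint=ckpt,
    )
    out_dir = Path(inf["output_dir"]) if inf["output_dir"] else config.model_dir / "output"
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, img in enumerate(images):
        vol = ImageVolume(np.asarray(img, dtype=np.float32).reshape(-1, 1, 1),
                          np.eye(4), section="inferred")
        path = out_dir / f"interp_{i:03d}.nii.gz"
        write_volume(vol, path)
        written.append(path)
    return written


def run(config: ConfigSpec):
    action = config.system["action"]
    if action == "train":
        return run_training(config)
    if action == "inference":
        return run_inference(config)
    if action == "evaluation":
        return run_evaluation(config)
    if action == "linear_interpolation":
        return run_linear_interpolation(config)
    raise DriverError(f"unknown action {action!r}")
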