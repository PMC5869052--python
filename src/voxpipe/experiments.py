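"""End-to-end recovery studies on synthetic phantoms.

These are the package's own benchmark experiments: train the reference
network on a handful of phantom subjects and measure how well held-out
structure is recovered.  Problem sizes are deliberately desk-scale — 32^3
volumes, 8 training / 2 held-out subjects, 16^3 windows, a few hundred
optimizer steps — so each study runs in minutes on one CPU.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .config import parse_config
from .driver import OUTPUT_SUFFIX, build_index, run_inference, run_training
from .evaluation import evaluate_subjects
from .phantoms import PhantomSpec, write_phantom_dataset
from .volume_io import load_volume

N_TRAIN = 8
N_HELD_OUT = 2


def _config_text(tmp: Path, seed: int, *, network: str, loss: str, n_classes: int,
                 iterations: int, train_ids: str, target_section: bool,
                 lr: float = 0.01) -> str:
    sections = f"""
[image]
csv_file = {tmp}/data/manifest.csv
subjects = {train_ids}
"""
    if target_section:
        sections += f"""
[target]
csv_file = {tmp}/data/manifest.csv
subjects = {train_ids}
"""
    else:
        sections += f"""
[label]
csv_file = {tmp}/data/manifest.csv
subjects = {train_ids}
"""
    return f"""
[system]
action = train
model_dir = {tmp}/model
seed = {seed}

[network]
name = {network}
n_classes = {n_classes}

[training]
iterations = {iterations}
lr = {lr}
loss = {loss}
spatial_window_size = 16 16 16
batch_size = 4
normalization = none
augmentation = yes
rotation_range_deg = -10 10
scaling_range_pct = 90 110
save_every = {iterations}

[inference]
sampler = grid
spatial_window_size = 16 16 16
border = 2 2 2
normalization = none
output_kind = {"continuous" if loss == "rmse" else "label"}
""" + sections


def segmentation_recovery(
    seed: int,
    n_organs: int = 3,
    noise_sd: float = 0.1,
    iterations: int = 500,
    work_dir: str | Path | None = None,
) -> dict[int, float]:
    """Train the reference segnet on phantom subjects, return held-out Dice.

    Conditions: 32^3 phantoms with ``n_organs`` organs at unit intensity
    separation and ``noise_sd`` Gaussian noise; 8 training and 2 held-out
    subjects; Dice loss with random affine augmentation; grid-sampled
    inference with border 2.  Returns {organ label: median held-out Dice}.
    """
    tmp = Path(work_dir) if work_dir else Path(tempfile.mkdtemp(prefix="voxpipe_seg_"))
    spec = PhantomSpec(shape=(32, 32, 32), n_organs=n_organs,
                       noise_sd=noise_sd, seed=seed)
    write_phantom_dataset(spec, N_TRAIN + N_HELD_OUT, tmp / "data")
    train_ids = " ".join(f"subject{i:03d}" for i in range(N_TRAIN))
    test_ids = " ".join(
        f"subject{i:03d}" for i in range(N_TRAIN, N_TRAIN + N_HELD_OUT))

    text = _config_text(tmp, seed, network="segnet", loss="dice",
                        n_classes=n_organs + 1, iterations=iterations,
                        train_ids=train_ids, target_section=False)
    cfg = parse_config(text=text)
    _, ckpt = run_training(cfg)

    inf_text = text.replace("action = train", "action = inference") \
                   .replace(f"subjects = {train_ids}", f"subjects = {test_ids}")
    inf_cfg = parse_config(text=inf_text)
    run_inference(inf_cfg, ckpt)
    report = evaluate_subjects(build_index(inf_cfg), tmp / "model" / "output",
                               metrics=("dice",))
    medians = report[report.subject_id == "median"].set_index("label")["value"]
    return {int(k): float(v) for k, v in medians.items()}


def regression_recovery(
    seed: int,
    n_organs: int = 3,
    noise_sd: float = 0.1,
    iterations: int = 300,
    work_dir: str | Path | None = None,
) -> dict[str, float]:
    """Train the regression net on phantom pairs, return held-out errors.

    Same phantom conditions as :func:`segmentation_recovery` but the target
    volume encodes a per-tissue intensity map of the organ index; training
    minimizes RMSE.  Returns voxelwise MAE/ME/RMSE over the held-out
    subjects plus the phantom noise level for reference.
    """
    tmp = Path(work_dir) if work_dir else Path(tempfile.mkdtemp(prefix="voxpipe_reg_"))
    spec = PhantomSpec(shape=(32, 32, 32), n_organs=n_organs,
                       noise_sd=noise_sd, seed=seed)
    write_phantom_dataset(spec, N_TRAIN + N_HELD_OUT, tmp / "data", kind="regression")
    train_ids = " ".join(f"subject{i:03d}" for i in range(N_TRAIN))
    test_ids = [f"subject{i:03d}" for i in range(N_TRAIN, N_TRAIN + N_HELD_OUT)]

    text = _config_text(tmp, seed, network="regression", loss="rmse",
                        n_classes=2, iterations=iterations,
                        train_ids=train_ids, target_section=True)
    cfg = parse_config(text=text)
    _, ckpt = run_training(cfg)

    inf_text = text.replace("action = train", "action = inference") \
                   .replace(f"subjects = {train_ids}", f"subjects = {' '.join(test_ids)}")
    run_inference(parse_config(text=inf_text), ckpt)

    errors = []
    for sid in test_ids:
        pred = np.squeeze(load_volume(tmp / "model" / "output" / f"{sid}{OUTPUT_SUFFIX}").data)
        target = np.squeeze(load_volume(tmp / "data" / f"{sid}_target.nii.gz").data)
        errors.append((pred - target).ravel())
    err = np.concatenate(errors)
    return {
        "mae": float(np.abs(err).mean()),
        "me": float(err.mean()),
        "rmse": float(np.sqrt((err ** 2).mean())),
        "noise_sd": noise_sd,
    }
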