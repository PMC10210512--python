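# ocra

An object-centric recurrent attention model for multiobject recognition and
same–different visual reasoning, with fully procedural stimulus generators.

At every timestep the model reads a variable-resolution glimpse from the
image through a grid of Gaussian filters whose pose (center, spacing,
width) is decoded from the previous decoder state; a small CNN and an
encoder LSTM turn the glimpse into features; primary capsules are read out
and dynamically routed — with max–min-normalized coupling coefficients —
into class capsules whose magnitudes accumulate into classification
scores; the most active capsule is masked through to a decoder LSTM that
plans the next glimpse and writes a patch to a reconstruction canvas.
Training combines a margin loss on cumulative capsule magnitudes with a
(optionally coverage-masked) mean-squared reconstruction loss.

The package is pure NumPy/SciPy: it includes a small reverse-mode autodiff
engine (`ocra.autodiff`) so the whole loop — including the attention
filterbank and the routing iterations — is differentiable end to end
without a deep-learning framework.

## Layout

| module | contents |
| --- | --- |
| `ocra.autodiff`, `ocra.nn` | tensor autodiff engine; Linear/LSTM/conv/pool layers, Adam |
| `ocra.attention` | four-parameter Gaussian filterbank: pose mapping, read, write, coverage |
| `ocra.routing` | max–min coupling normalization, squash, routing by agreement, capsule masking |
| `ocra.model` | model assembly, timestep loop, ablation variants, decision rules |
| `ocra.losses` | margin / reconstruction / combined losses |
| `ocra.stimuli` | fixture glyphs, overlapping-digit and cluttered-scene generators, same–different shape generator, PNG+CSV manifest I/O |
| `ocra.harness` | run configs, parameter accounting, training loop, evaluation, visualization |
| `ocra.cli` | `ocra` command-line entry point |

## CLI

```sh
# procedural datasets (PNG images + CSV manifest); no downloads needed
ocra generate --task multimnist --n 2000 --seed 0 --out data/mm --split train
ocra generate --task svrt1 --n 2000 --seed 0 --out data/svrt

# training from a YAML run config (see configs/ for smoke and full-scale)
ocra train --config configs/smoke_multimnist.yaml

# evaluation, parameter accounting, glimpse-trajectory panels
ocra eval --ckpt runs/smoke_multimnist/checkpoint.npz --data data/mm --split test
ocra count-params --task multimnist            # -> 3,873,260 (3.87M)
ocra viz --ckpt runs/smoke_multimnist/checkpoint.npz \
         --image data/mm/images/train_000000.png --out viz/
```

The digit benchmarks default to the built-in procedural glyph source; pass
`--digit-source <dir>` with IDX-format handwritten-digit files to generate
from the real dataset instead (train/test splits are kept separated).

`configs/` ships both smoke-scale profiles (CPU, minutes) and the exact
full-scale profiles for the reported benchmark runs (millions of images,
five seeds); the latter are not expected to be reproduced on a desktop.

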