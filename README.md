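# soilct

Surrogate-annotated deep-learning analysis of X-ray CT volumes of soil
cores, exercised end-to-end on a seeded synthetic soil-volume generator.

The pipeline:

1. **volume I/O** — read a DICOM slice series (or raw voxel stream), shift
   Hounsfield units by +2048 into [0, 6144], crop to the centered inner
   analysis region (default 400×200×200).
2. **object classes** — partition the HU range into six 1024-wide bands
   ("object classes"), binarize a volume with selected classes as the solid
   phase (0 = void, 1 = solid), trim solid clusters smaller than 60 voxels,
   and compute per-slice porosity `Area(void) / (Area(void)+Area(solid))`
   along the core axis. These porosity profiles are the *surrogate
   annotation* — no manual labels anywhere.
3. **synthetic data** — seeded generator of soil-like volumes (matrix,
   pores, organic blobs, stones, meandering tunnels) with exact per-voxel
   material labels, so every downstream stage has an exact oracle.
4. **surrogate training** — band-stacked 3-channel slice images
   (object1+2 / 3+4 / 5+6) regressed onto slice porosity with a VGG-style
   CNN (`scale="mini"` for CPU work, `scale="full"` for the 13-conv +
   3-dense reference topology ending in a single scalar unit). 80/20
   seeded split, MSE loss, Adam, early stopping.
5. **transfer** — freeze the conv stack, re-train only the dense head on a
   different porosity target; conv weights are asserted bit-identical.
6. **compatibility** — apply every model to every sample, build the RMSE
   matrix, and greedily select representative models covering the most
   samples at RMSE < 0.04.
7. **grad-CAM** — gradient-based class activation maps for the scalar
   regression output, for any conv layer.

The CNN engine (`soilct/nn.py`) and a minimal DICOM explicit-VR-LE codec
(`soilct/dicom_lite.py`) are implemented on numpy because no deep-learning
or DICOM library is available in the target environment.

## CLI

```sh
soilct simulate --seed 1 --out-dir runs/sim                 # synthetic cores
soilct annotate --volume runs/sim/sim1.raw --out-dir runs/ann
soilct train    --volume runs/sim/sim1.raw --seed 1 --out-dir runs/train
soilct transfer --volume runs/sim/sim1.raw --model runs/train/model.npz \
                --seed 1 --out-dir runs/transfer
soilct compat   --models runs/train/model.npz --volumes runs/sim/sim*.raw \
                --out-dir runs/compat
soilct gradcam  --volume runs/sim/sim1.raw --model runs/train/model.npz \
                --slice-index 10 --out-dir runs/cam
```

Every subcommand accepts `--config <yaml>` (defaults cover the band
scheme, 60-voxel trim, 0.8 split fraction, 0.04 compatibility threshold
and crop extents), writes its artifacts plus a `manifest.json` (config
snapshot, seed, versions, input digests) into `--out-dir`, and is fully
reproducible for a fixed seed.

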