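# acrcnr

Automatic contrast-to-noise ratio (CNR) measurement for low-contrast-module
images of the ACR CT phantom.

## The problem

CT quality-control programs evaluate low-contrast detectability on the ACR
accreditation phantom, whose module 2 contains a 25 mm cylinder differing
from the water-equivalent background by only ~6 HU. The CNR of that object,

```
CNR = (CT̄_object − CT̄_background) / SD_background
```

is checked against the accreditation tolerance CNR ≥ 1.0. Placing the two
circular ROIs by hand is slow and subjective; `acrcnr` automates it for
medical physicists and QC technologists.

## The method

The 25 mm object always sits **55 mm** from the phantom center, but its
angular position — and the phantom's alignment in the gantry — varies scan
to scan. The statistical localization exploits this:

1. segment the phantom body from air (threshold −300 HU, largest connected
   component, holes filled) and take its binary centroid;
2. place a 25 mm circular ROI 55 mm from the centroid and rotate it
   clockwise in 2° steps through a full revolution, recording the mean CT
   number at each step (the *angular profile*);
3. the profile maximum marks the object; a background ROI at the centroid
   supplies CT̄_background and SD_background, and the CNR follows from the
   equation above.

Because the search is anchored to the *measured* centroid, the method
tolerates phantom misalignment of many millimetres.

A synthetic phantom generator (`acrcnr.synthetic`) renders module-2-like
slices — 200 mm body at 90 HU in air, a 25 mm disc of configurable contrast
at 55 mm radius, area-fraction antialiased edges, white Gaussian noise —
with full ground truth, so localization and CNR recovery are testable
without scanner data.

## Worked example

```python
from acrcnr import PhantomCNR
from acrcnr.synthetic import SyntheticPhantomConfig, generate_stack

cfg = SyntheticPhantomConfig(n_slices=5, seed=3, object_angle_deg=250.0,
                             offset_mm=(3.0, -2.0))          # 3.6 mm misaligned
images = [im for im, _ in generate_stack(cfg)]
results = PhantomCNR(images, label="synthetic, contrast 6 HU / noise 3 HU").fit()
print(results.summary())
```

prints

```
Automatic CNR measurement — synthetic, contrast 6 HU / noise 3 HU
============================================================
slices: 5    search: radius 55 mm, ROI 25 mm, step 2 deg, background ROI 25 mm
------------------------------------------------------------
                    mean        sd
contrast (HU)        6.0       0.1
noise (HU)           3.0       0.0
CNR                  2.0       0.1
------------------------------------------------------------
tolerance (CNR >= 1): PASS
detected object angle: 250.0 deg (sd 0.00)
```

The generator drew the object at 250° with +6 HU contrast on 3 HU noise;
the automatic search recovered the angle exactly on every slice, the
measured contrast and noise match the ground truth, and the mean CNR of
2.0 (= 6/3) passes the accreditation tolerance. Real scans are measured the
same way from DICOM:

```python
results = PhantomCNR.from_dicom_dir("scan_directory/", label="120 kV").fit()
results.save_csv("results.csv")
results.plot_overlay(0)       # slice with both ROIs drawn
```

Or from the shell:

```bash
acrcnr simulate --config cfg.txt --out stack/    # synthetic DICOM stack
acrcnr measure stack/ --out results.csv          # automatic measurement
acrcnr measure stack/ --object-center 175.0,65.4 --background-center 117.2,115.3
acrcnr compare auto.csv manual.csv --field cnr   # % difference + rank-sum test
```

`measure` exits 0 on success, 2 when no phantom is found, 3 on degenerate
statistics (e.g. a noiseless image, where CNR is undefined) and 4 on I/O
errors.

## Documentation

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations of the synthetic generator.
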