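# prostmould

Patient-specific, 3D-printable prostate biopsy moulds with calibrated
needle guides, generated from MRI surface segmentations.

## The problem

After a radical prostatectomy the explanted prostate contains lesions that
were segmented on MRI and biopsy-proven during the diagnostic workup, but the
cancerous tissue is visually indistinguishable from benign gland.  Procuring
fresh, viable tumour tissue for research therefore needs image guidance —
without disturbing the standard pathology workflow.  One practical answer is
a bespoke mould: a printed block whose cavity matches the patient's prostate
boundary segmentation, with cylindrical guide channels aimed so that a core
needle inserted to a fixed depth samples each MRI-defined region of interest
(ROI) at its centre of mass.

`prostmould` implements that pipeline as a library and CLI, for engineers and
researchers building ex vivo sampling platforms:

- **mesh I/O** — STL read/write (binary and ASCII, millimetres, LPS
  anatomical frame), validation and repair limited to vertex merging and
  winding; holes are treated as data errors.
- **mould construction** — signed-distance-field CSG: the cavity is the
  boundary surface (optionally offset outward 1–2 mm to tolerate
  segmentation error), subtracted from a material-optimised block (bounding
  box + wall margin) together with a specimen-insertion opening and the guide
  channels; surfaces are recovered by marching cubes, so every emitted solid
  is watertight (printable) by construction.
- **guide calibration** — each guide's axis is a block-face normal through
  the ROI centroid, and its length satisfies
  `entry→centroid = insertion_depth − tip_to_notch_center`
  (default insertion depth 50 mm), with a support tower above the face when
  the target is shallow and a hard error when it is unreachable.
- **targeting simulation** — the needle notch is clipped against the ROI
  surface, exactly at zero error and by seeded Monte-Carlo under rigid
  placement/segmentation jitter, with an analytic Gaussian-displacement
  oracle for spherical ROIs.
- **synthetic cases** — seeded ellipsoid/sphere phantoms emulating
  fusion-biopsy exports (prostates 25.5–55.4 ml, ROIs 0.13–2.41 ml), so every
  stage is testable without clinical data.
- **cohort summary** — medians, positivity and Gleason-grade concordance of
  a packaged 12-patient feasibility cohort table.

## Worked example

```python
import prostmould as pm

# a synthetic patient: 33 ml ellipsoid prostate, one 5 mm-radius ROI
case = pm.generate_phantom(pm.PhantomSpec(
    roi_specs=[pm.RoiSpec("roi_1", (5, -3, 4), radius_mm=5.0)], seed=1))

variants = pm.build_mould_variants(case.case, pm.MouldSpec())
for m in variants:
    print(f"offset {m.variant_offset_mm:g} mm: "
          f"solid {m.solid_volume_mm3:.0f} mm3, "
          f"cavity {m.cavity_volume_mm3:.0f} mm3, guides {len(m.guides)}")

report = pm.simulate_insertion(variants[0], variants[0].guides[0],
                               case.rois["roi_1"])
print(f"axis-to-centroid {report.axis_to_centroid_mm:.2e} mm, "
      f"notch-ROI intersection {report.notch_roi_intersection_mm:.2f} mm, "
      f"hit {report.hit}")
```

prints

```
offset 0 mm: solid 160597 mm3, cavity 33093 mm3, guides 2
offset 1 mm: solid 154191 mm3, cavity 38363 mm3, guides 2
offset 2 mm: solid 147343 mm3, cavity 44161 mm3, guides 2
axis-to-centroid 0.00e+00 mm, notch-ROI intersection 10.00 mm, hit True
```

Three mould variants are built per case (cavity offsets 0, 1, 2 mm) sharing
one guide plan; the solid shrinks as the cavity grows.  The zero-error
needle axis passes exactly through the ROI centroid and the notch captures a
10 mm chord — the full diameter of the 5 mm ROI, as the calibration identity
guarantees.

The same pipeline is scriptable from a shell:

```sh
prostmould gen-phantom --out cases --seed 7 --n-cases 1
prostmould build-mould --case-dir cases/cohort_7_00 --out moulds
prostmould validate-targeting --case-dir cases/cohort_7_00 --out report.json
prostmould summarize-cohort
```

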