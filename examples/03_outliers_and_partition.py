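"""Screen spectral outliers and build a Kennard-Stone partition.

Mahalanobis distances are computed in a 5-dimensional PCA score space
(full-channel covariance is singular when channels outnumber samples);
samples beyond mean + 3 sd are flagged.  Kennard-Stone then picks a
calibration set that spans the spectral space.
"""

from nirquant import SyntheticConfig, generate, kennard_stone, mahalanobis_screen

dataset = generate(SyntheticConfig(n_samples=120, n_channels=1557, seed=4))

report = mahalanobis_screen(dataset.spectra, k_components=5, sd_multiplier=3.0)
print(f"outlier screen: threshold {report.threshold:.2f}, "
      f"flagged {len(report.flagged_ids)} of {dataset.spectra.n_samples} "
      f"samples {list(report.flagged_ids)}")

retained = dataset.spectra.select_samples(report.retained_ids)
n_cal = int(round(0.8 * retained.n_samples))
partition = kennard_stone(retained, n_cal)
print(f"Kennard-Stone: {len(partition.calibration_ids)} calibration / "
      f"{len(partition.prediction_ids)} prediction")
print(f"first selected (most distant pair): {partition.order_selected[:2]}")

cal = dataset.references.loc[list(partition.calibration_ids)]
pred = dataset.references.loc[list(partition.prediction_ids)]
for analyte in ("total_saponins", "mannitol", "naringenin"):
    print(f"  {analyte:15s} calibration range "
          f"[{cal[analyte].min():.4f}, {cal[analyte].max():.4f}]  "
          f"prediction range [{pred[analyte].min():.4f}, {pred[analyte].max():.4f}]")
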