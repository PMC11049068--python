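"""Calibrate a PLS1 model with leave-one-out cross-validation.

The RMSECV-versus-components curve identifies the latent-variable count
that balances underfitting against overfitting; the final model predicts
with a single matrix-vector product.
"""

import numpy as np

from nirquant import (SyntheticConfig, generate, kennard_stone, loocv_rmsecv,
                      pls_fit, r_squared, rmse)

dataset = generate(SyntheticConfig(n_samples=120, n_channels=400, seed=2))
partition = kennard_stone(dataset.spectra, 96)
cal = dataset.spectra.select_samples(partition.calibration_ids)
pred = dataset.spectra.select_samples(partition.prediction_ids)
y_cal = dataset.references.loc[list(partition.calibration_ids), "mannitol"].to_numpy()
y_pred = dataset.references.loc[list(partition.prediction_ids), "mannitol"].to_numpy()

cv = loocv_rmsecv(cal.absorbance, y_cal, a_max=10)
print("RMSECV (g/kg) by number of latent variables:")
for a, v in enumerate(cv.rmsecv_by_components, start=1):
    marker = "  <- optimal" if a == cv.optimal_components else ""
    print(f"  A={a:2d}  {v:.4f}{marker}")

model = pls_fit(cal.absorbance, y_cal, cv.optimal_components)
yhat = model.predict(pred.absorbance)
print(f"\nprediction set ({len(y_pred)} samples): "
      f"RMSEP = {rmse(yhat, y_pred):.4f} g/kg, "
      f"R_p^2 = {r_squared(yhat, y_pred, 'eq9_pred'):.4f}")
print(f"largest |coefficient| at "
      f"{pred.wavelengths_nm[int(np.argmax(np.abs(model.coefficients)))]:.0f} nm "
      "(inside the mannitol band)")
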