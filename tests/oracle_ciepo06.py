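"""Independent transcription of the average-observer recipe.

A deliberately flat, single-pass reimplementation of the zero-deviation
computation (age-scaled lens density, field-size-scaled macular and pigment
peak densities, self-screening absorptance, quanta-to-energy conversion,
unit-peak normalization), used as the oracle for the model's zero-deviation
reduction.  It shares only the basis tables with the implementation under
test, not any of its code paths.
"""

import numpy as np


def ciepo06_fundamentals(age, field_size, basis):
    """(3, n) unit-peak l/m/s for the average observer at (age, field size)."""
    grid = basis.grid
    if age <= 60:
        aging = 1.0 + 0.02 * (age - 32.0)
    else:
        aging = 1.56 + 0.0667 * (age - 60.0)
    d_ocul = basis.docul1 * aging + basis.docul2
    d_macula = 0.485 * np.exp(-field_size / 6.132) * basis.d_rel_macula
    filters = 10.0 ** (-(d_macula + d_ocul))
    d_max_lm = 0.38 + 0.54 * np.exp(-field_size / 1.333)
    d_max_s = 0.30 + 0.45 * np.exp(-field_size / 1.333)
    rows = []
    for absorbance, d_max in (
        (basis.absorbance_L, d_max_lm),
        (basis.absorbance_M, d_max_lm),
        (basis.absorbance_S, d_max_s),
    ):
        absorptance = 1.0 - 10.0 ** (-d_max * absorbance)
        quanta = absorptance * filters
        energy = grid * quanta
        rows.append(energy / energy.max())
    return np.vstack(rows)
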