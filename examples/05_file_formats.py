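"""Reading and writing spectra: CSV matrix, JCAMP-DX and HDF5."""

import tempfile
from pathlib import Path

from marginspec import (
    GeneratorConfig,
    default_ftir_model,
    read_hdf5,
    read_jcamp,
    read_matrix,
    sample_dataset,
    write_hdf5,
    write_matrix,
)

ds = sample_dataset(default_ftir_model(), GeneratorConfig(seed=3, n_per_class=5))
tmp = Path(tempfile.mkdtemp())

csv_path = tmp / "spectra.csv"
write_matrix(ds, csv_path)
back = read_matrix(csv_path, "ftir")
print(f"CSV round-trip: {len(back)} spectra, axis {len(back.axis)} points, "
      f"metadata columns {list(back.meta.columns)}")

h5_path = tmp / "spectra.h5"
write_hdf5(ds, h5_path)
print(f"HDF5 round-trip: {len(read_hdf5(h5_path))} spectra")

jdx = tmp / "one.jdx"
jdx.write_text(
    "##TITLE=demo\n##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n"
    "##XFACTOR=1.0\n##YFACTOR=0.01\n##FIRSTX=1700\n##LASTX=1716\n"
    "##NPOINTS=5\n##XYDATA=(X++(Y..Y))\n1700 1 2 3\n1712 4 5\n##END=\n"
)
s = read_jcamp(jdx)
print(f"JCAMP-DX: {len(s.axis)} points from {s.axis.lo:.0f} to "
      f"{s.axis.hi:.0f} cm^-1, intensities {s.intensity.tolist()}")
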