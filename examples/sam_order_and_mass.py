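"""Chain order parameters and Sauerbrey mass for monolayer QC.

The alkanethiol chain tilt of a well-packed COOH-OEG-SAM lies around
20-35 degrees from the surface normal; the corresponding second-order
Legendre order parameter S = (3 cos^2 theta - 1)/2 is the quantity a
simulation reports.  The Sauerbrey relation converts a QCM-D frequency
shift into an areal mass for rigidly coupled films.
"""

from refloat.biophys import (
    QcmReading,
    order_parameter_to_tilt,
    sauerbrey_mass,
    tilt_to_order_parameter,
)

print("tilt angle -> order parameter:")
for theta in (0.0, 20.0, 35.0, 54.7):
    print(f"  {theta:5.1f} deg -> S = {tilt_to_order_parameter(theta):.2f}")

print(f"S = 0.65 corresponds to a tilt of "
      f"{order_parameter_to_tilt(0.65):.1f} deg")

# a -30 Hz shift on the 3rd overtone of a 5 MHz crystal (C = 17.7)
reading = QcmReading(df=-30.0, overtone=3, sensitivity_constant=17.7)
print(f"Sauerbrey mass for df3 = -30 Hz: {sauerbrey_mass(reading):.0f} ng/cm^2")
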