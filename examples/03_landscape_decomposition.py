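"""Energy landscape of a genome and its periodic/smooth decomposition.

Scores every 147-bp window of a 2 kb random genome with the toy model's
exact free energy, Boltzmann-normalizes the landscape, and splits it into
an 11-bp local average (the slowly varying component) and the periodic
component dominated by the ~10-bp helical repeat imposed by the constraint
profile of the model.
"""

import numpy as np

import nucleomark as nm
from nucleomark.landscape import local_average, normalize_landscape, periodic_component

toy = nm.default_toy_model()
genome = nm.random_genome(2_000, seed=7)

ls = normalize_landscape(nm.compute_landscape(genome, toy))
avg = local_average(ls)
per = periodic_component(ls)

print(f"windows scored          : {len(ls)}")
print(f"landscape mean / spread : {ls.values.mean():.2f} / {ls.values.std():.2f} kT_room")
print(f"local-average spread    : {avg.values.std():.2f} kT_room")
print(f"periodic-component RMS  : {np.sqrt((per.values**2).mean()):.2f} kT_room")

# dominant period of the periodic component via the discrete spectrum
freqs = np.fft.rfftfreq(len(per), d=1.0)
power = np.abs(np.fft.rfft(per.values)) ** 2
peak = freqs[1:][np.argmax(power[1:])]
print(f"dominant period         : {1/peak:.1f} bp (constraint profile period: {toy.period} bp)")
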