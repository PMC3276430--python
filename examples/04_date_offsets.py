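"""De-identify dates: one encrypted base date, everything else as day offsets.

Analysts see only the offsets — every between-date interval is preserved
exactly, but no calendar position is revealed. A key holder reconstructs
true dates by decrypting the base.
"""

import datetime as dt

import phicrypt as pc

key = pc.derive_key("hunter2")

visits = {
    "diagnosis": dt.date(2009, 3, 14),
    "admission": dt.date(2009, 4, 2),
    "discharge": dt.date(2009, 4, 11),
}
record = pc.encode_dates(visits, base=dt.date(2009, 1, 1), key=key)

print("stored offsets (analyst view):", dict(record.offsets))
print("stored base (server view)    :", record.base_cipher)
print("admission - diagnosis        :",
      record.offsets["admission"] - record.offsets["diagnosis"], "days (from offsets alone)")

decoded = pc.decode_dates(record, key)
print("decoded with the key         :", {k: str(v) for k, v in decoded.items()})

# The base date is arbitrary: any base gives the same decoded dates.
other = pc.encode_dates(visits, base=dt.date(1987, 6, 5), key=key)
print("same dates from another base :", pc.decode_dates(other, key) == decoded)
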