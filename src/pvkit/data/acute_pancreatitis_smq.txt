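# Acute pancreatitis preferred-term list (SMQ-style, editable).
# One preferred term per line; matching is case-insensitive exact.
# The broad section may be empty; narrow terms always count as broad too.
[narrow]
Pancreatitis acute
Pancreatitis
Pancreatitis necrotising
Pancreatitis haemorrhagic
Oedematous pancreatitis
Pancreatic necrosis
[broad]
Lipase increased
Amylase increased
Abdominal pain upper
Pancreatic enzymes increased
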