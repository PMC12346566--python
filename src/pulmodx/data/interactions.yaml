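# High-risk drug interaction screen: 25 anticoagulant-centered pairs.
# If an assigned drug pairs with the patient's background medication, the
# formulary rule's alternate is dispensed instead.
anticoagulants: [Warfarin, Apixaban, Rivaroxaban, Dabigatran, Edoxaban]
interacting_drugs: [Ibuprofen, Azithromycin, Doxycycline, Aspirin, Clarithromycin]
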