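>MTBD_synthetic|residues 59-170|synthetic stand-in sequence for the MAP7 microtubule-binding domain
PVLEVDDREKLAEKQKEAEKRELAAREIVWKEREEKARELYEKELEKREKAEQERKELEE
KRKAEEEKARKELEEKQKREEKAVVRRTMERSEKPKQEANRSGEKEELHSQP
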