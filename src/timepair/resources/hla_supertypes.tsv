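allele	supertype
A*01:01	A01
A*26:01	A01
A*30:02	A01
A*32:01	A01
A*02:01	A02
A*02:02	A02
A*02:03	A02
A*02:05	A02
A*02:06	A02
A*02:07	A02
A*68:02	A02
A*03:01	A03
A*11:01	A03
A*11:02	A03
A*30:01	A03
A*31:01	A03
A*33:01	A03
A*33:03	A03
A*66:01	A03
A*68:01	A03
A*74:01	A03
A*23:01	A24
A*24:02	A24
A*24:03	A24
B*07:02	B07
B*35:01	B07
B*35:03	B07
B*51:01	B07
B*51:02	B07
B*53:01	B07
B*54:01	B07
B*55:01	B07
B*55:02	B07
B*56:01	B07
B*67:01	B07
B*08:01	B08
B*14:02	B27
B*15:09	B27
B*27:02	B27
B*27:05	B27
B*38:01	B27
B*39:01	B27
B*39:09	B27
B*48:01	B27
B*73:01	B27
B*18:01	B44
B*37:01	B44
B*40:01	B44
B*40:02	B44
B*40:06	B44
B*44:02	B44
B*44:03	B44
B*45:01	B44
B*50:01	B44
B*57:01	B58
B*57:02	B58
B*58:01	B58
B*58:02	B58
B*13:01	B62
B*13:02	B62
B*15:01	B62
B*15:02	B62
B*15:12	B62
B*15:13	B62
B*15:25	B62
B*46:01	B62
B*52:01	B62
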