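congener,new,pPA2,pFLU,pDAD,pANA,pHAL,pAMB,pBUG
C4-C10,1,,,,0.1,,,
C6-C10,0,,,,0.1,,,
C8-C10,0,4.1,0.1,1.9,5.5,,,
C9-C10,0,,,,0.1,,,
C8-C12,0,0.3,,0.3,0.3,,,
C10-C10,0,49.5,3.0,4.5,31.3,,,
C8-C12:1,0,,,0.1,0.3,,,
C10-C10:1,0,0.3,,,0.2,,,
C10-C11,0,,,,0.1,,,
C8-C14,1,0.3,,,,0.3,,0.2
C10-C12,0,32.5,17.1,7.1,16.4,0.1,0.3,0.2
C8-C14:1,1,,0.4,,,0.1,,0.1
C10-C12:1,0,4.2,21.3,5.6,10.7,,,
C10-C13,1,,0.3,0.3,0.2,,0.1,
C10-C14,0,4.1,23.8,25.8,10.0,2.0,2.3,4.5
C12-C12,0,0.4,1.0,,1.5,0.5,0.2,0.1
C10-C14:1,0,2.9,25.2,47.4,10.8,2.0,0.6,3.0
C12-C12:1,0,,,,1.5,,,
C10:1-C14:1,0,,,0.2,,,,
C11-C14,1,,,,,,0.3,0.1
C12-C13,1,,,,,0.1,0.6,
C10-C15:1,1,,,0.1,,,,
C11-C14:1,1,,,,,,0.1,
C10-C16,0,,0.2,,0.1,,,
C12-C14,0,,1.2,1.2,1.5,10.1,12.1,5.1
C13-C13,1,,,,,0.2,1.2,
C10-C16:1,0,,4.1,2.6,3.3,0.1,0.1,0.4
C12-C14:1,0,,1.2,1.6,2.2,8.8,4.9,3.9
C12:1-C14:1,0,,0.3,0.6,0.7,0.1,,0.1
C12-C15,1,,,,,,0.1,
C13-C14,0,,,,,0.4,6.3,0.6
C13-C14:1,1,,,,,0.3,4.0,0.4
C14-C14,0,,,,0.1,22.1,12.2,24.4
C10-C18:1,1,,0.4,,0.7,,,
C12-C16:1,1,,0.2,0.1,0.3,0.3,,0.3
C14-C14:1,0,,,0.1,0.4,30.8,36.5,28.3
C12:1-C16:1,1,,,,0.2,,,
C14:1-C14:1,0,,,0.2,0.2,14.9,10.3,11.7
C13-C16,1,,,,,0.1,,
C14-C15,0,,,,,,,0.3
C13-C16:1,1,,,,,,0.2,
C14-C15:1,1,,,,,0.1,0.5,0.2
C14:1-C15,1,,,,,,0.5,
C14:1-C15:1,1,,,,,,0.4,
C14-C16,0,,,,,0.5,,1.2
C12-C18:1,1,,,,0.1,,,
C14-C16:1,0,,,,0.2,3.5,1.7,8.9
C12:1-C18:1,1,,,,0.1,,,
C14:1-C16:1,1,,,,0.2,2.1,4.2,4.4
C14-C18:1,0,,,,,,,0.5
C16-C16:1,0,,,,,0.1,,0.1
C14:1-C18:1,1,,,,0.1,0.1,,0.4
C16:1-C16:1,0,,,,,0.1,,0.2
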