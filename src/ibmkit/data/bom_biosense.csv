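name,quantity,unit_price,cost
Espressif ESP32 PICO Kit,1,10.00,10.00
Adafruit MPU6050 Accelerometer/Gyroscope,2,6.99,13.98
Adafruit SSD1306 OLED Display,1,2.40,2.40
microSD card reader (SPI),1,1.39,1.39
Energizer 9 V lithium battery,1,14.97,14.97
Sparkfun SEN-15129,1,42.95,42.95
SPST Switch,1,0.95,0.95
Red LED,1,0.04,0.04
Enclosure,1,8.29,8.29
Dual-layer PCB fabrication,1,8.87,8.87
Wiring harness (per ft),4,0.24,0.94
Elastic band (per ft),4,0.06,0.24
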